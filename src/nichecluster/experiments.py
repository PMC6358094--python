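"""Scenario configuration, replicate execution and summary tables.

A :class:`ScenarioConfig` names one model scenario (defaults anchored to
a Barro Colorado Island-sized community: J = 21,000 individuals,
immigration rate m = 0.08, regional pool with theta = 50 and 150,000
individuals, about 400 species).  :func:`run_scenario` runs seeded
replicates, scores each final community with both clustering metrics
against abundance-shuffled nulls, and aggregates detection percentages
and mean z-scores; :func:`sweep` repeats that along an immigration-rate
or regional-diversity axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .compcol import (
    CCParams,
    deterministic_dynamics,
    displacement_matrix,
    fecundity_grid,
    fecundity_to_trait,
    simulate_compcol,
)
from .habitat import run_spatial
from .lotka_volterra import LVParams, simulate_lv
from .lottery import Community
from .metrics import (
    MetricResult,
    kmeans_gap_metric,
    make_nulls,
    ripley_gap_metric,
)
from .pool import RegionalPool, generate_pool
from .resources import ResourceParams, run_coupled

__all__ = [
    "ScenarioConfig",
    "ReplicateSummary",
    "run_scenario",
    "sweep",
    "make_fixture",
]

MODELS = ("lv", "neutral", "lv_filter", "resource", "habitat", "compcol")

M_SWEEP = (0.005, 0.01, 0.05, 0.08, 0.15)
THETA_SWEEP = (5, 10, 20, 30, 50)


@dataclass
class ScenarioConfig:
    """One simulation scenario plus metric settings."""

    model: str = "lv"
    params: dict = field(default_factory=dict)
    J: int = 21000
    m: float = 0.08
    theta: float = 50.0
    metacommunity_size: int = 150000
    generations: float = 100.0
    n_replicates: int = 10
    n_nulls: int = 100
    k_max: int = 20
    base_seed: int = 1
    L: int = 1000  # habitat model only

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must be in [0, 1]")
        if self.J < 1 or self.n_replicates < 1:
            raise ValueError("J and n_replicates must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class ReplicateSummary:
    """Aggregate of one scenario's replicates."""

    config: ScenarioConfig
    kmeans: list[MetricResult]
    ripley: list[MetricResult]
    failures: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return max(len(self.kmeans), len(self.ripley))

    def percent_significant(self, method: str = "kmeans") -> float:
        results = {"kmeans": self.kmeans, "ripley": self.ripley}[method]
        if not results:
            return float("nan")
        return 100.0 * float(np.mean([r.significant for r in results]))

    @property
    def percent_significant_either(self) -> float:
        either = [
            a.significant or b.significant
            for a, b in zip(self.kmeans, self.ripley)
        ]
        return 100.0 * float(np.mean(either))

    def mean_z(self, method: str = "ripley") -> tuple[float, float]:
        """Mean z with 1.96 standard errors of the mean."""
        zs = np.array(
            [
                r.z
                for r in {"kmeans": self.kmeans, "ripley": self.ripley}[method]
                if r.z is not None
            ]
        )
        if zs.size == 0:
            return float("nan"), float("nan")
        se = zs.std(ddof=1) / np.sqrt(zs.size) if zs.size > 1 else np.nan
        return float(zs.mean()), float(1.96 * se)

    def modal_k(self) -> Optional[int]:
        if not self.kmeans:
            return None
        ks = np.array([r.k_est for r in self.kmeans])
        values, counts = np.unique(ks, return_counts=True)
        return int(values[np.argmax(counts)])

    def to_dict(self) -> dict:
        mz_k = self.mean_z("kmeans")
        mz_r = self.mean_z("ripley")
        return {
            "model": self.config.model,
            "n_replicates": self.n,
            "percent_significant_kmeans": self.percent_significant("kmeans"),
            "percent_significant_ripley": self.percent_significant("ripley"),
            "percent_significant_either": self.percent_significant_either,
            "mean_z_kmeans": mz_k[0],
            "ci95_z_kmeans": mz_k[1],
            "mean_z_ripley": mz_r[0],
            "ci95_z_ripley": mz_r[1],
            "modal_k_est": self.modal_k(),
            "failures": self.failures,
        }


def _replicate_seeds(base_seed: int, idx: int, n_streams: int) -> list[int]:
    """idx 0 is reserved for the pool; replicate r uses idx r + 1."""
    ss = np.random.SeedSequence([base_seed, idx])
    return [int(s) for s in ss.generate_state(n_streams) % (2**31)]


def simulate_replicate(config: ScenarioConfig, pool: RegionalPool, seed: int) -> Community:
    """Run one replicate of the configured model to its final state."""
    model = config.model
    p = config.params
    if model == "lv":
        params = LVParams(w=p.get("w", 0.063))
        return simulate_lv(pool, params, config.J, config.m, config.generations, seed)
    if model == "neutral":
        params = LVParams(r=np.ones(pool.S))
        return simulate_lv(
            pool, params, config.J, config.m, config.generations, seed,
            neutral_kernel=True,
        )
    if model == "lv_filter":
        params = LVParams(
            filter_profile=p.get("filter", "quadratic"),
            filter_sigma=p.get("filter_sigma"),
        )
        return simulate_lv(
            pool, params, config.J, config.m, config.generations, seed,
            neutral_kernel=True,
        )
    if model == "resource":
        params = ResourceParams(
            sigma=p.get("sigma", 0.03),
            K=p.get("K", 400),
            n_resources=p.get("n_resources", 500),
            rho=p.get("rho", 1),
        )
        snaps = run_coupled(
            pool, params, config.J, config.m, config.generations, seed
        )
        return snaps[-1][0]
    if model == "habitat":
        snaps = run_spatial(
            pool,
            sigma=p.get("sigma", 0.07),
            d_disp=p.get("d_disp", 1e5),
            m=config.m,
            generations=config.generations,
            seed=seed,
            L=config.L,
        )
        return snaps[-1].abundances()
    if model == "compcol":
        params = CCParams(s=p.get("s", 0.15), mu=p.get("mu", 1.0))
        return simulate_compcol(
            pool, params, config.J, config.m, config.generations, seed
        )
    raise ValueError(f"unknown model {model!r}")


def run_scenario(
    config: ScenarioConfig,
    out_dir: Optional[str | Path] = None,
    methods: Sequence[str] = ("kmeans", "ripley"),
) -> ReplicateSummary:
    """Run all replicates of a scenario and score the clustering metrics.

    Replicate r uses dynamics seeds derived from (base_seed, r); null
    shuffles use an independent stream.  Each replicate assembles its own
    regional pool: a single shared pool would carry one fixed chance
    association between traits and regional abundances into every
    replicate, correlating their metric scores instead of averaging the
    pool-level noise out.  ``methods`` restricts which metrics are
    evaluated (sweeps need only Ripley z-scores).  With ``out_dir``,
    community tables and metric results are persisted per replicate.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary = ReplicateSummary(config=config, kmeans=[], ripley=[])
    for rep in range(config.n_replicates):
        pool_seed, sim_seed, null_seed = _replicate_seeds(
            config.base_seed, rep + 1, 3
        )
        try:
            pool = generate_pool(
                config.theta, config.metacommunity_size, pool_seed
            )
            community = simulate_replicate(config, pool, sim_seed)
            cpool = community.pool  # compcol swaps in the tradeoff axis
            rng = np.random.default_rng(null_seed)
            nulls = make_nulls(community.N, cpool, config.n_nulls, rng)
            km = rp = None
            if "kmeans" in methods:
                km = kmeans_gap_metric(
                    community, cpool, k_max=config.k_max, nulls=nulls
                )
            if "ripley" in methods:
                rp = ripley_gap_metric(community, cpool, nulls=nulls)
        except Exception as exc:  # noqa: BLE001 - surfaced in the summary
            summary.failures.append(f"replicate {rep}: {exc}")
            warnings.warn(f"replicate {rep} failed: {exc}", stacklevel=2)
            continue
        if km is not None:
            summary.kmeans.append(km)
        if rp is not None:
            summary.ripley.append(rp)
        if out is not None:
            meta = {"replicate": rep, "seed": sim_seed, **asdict(config)}
            cpool.save(out / f"pool_{rep:03d}.csv")
            community.save(out / f"community_{rep:03d}.csv", metadata=meta)
            if km is not None:
                km.save(out / f"kmeans_{rep:03d}.json")
            if rp is not None:
                rp.save(out / f"ripley_{rep:03d}.json")
    if summary.failures:
        warnings.warn(
            f"{len(summary.failures)} replicate(s) failed; summary covers "
            f"{summary.n} completed replicates",
            stacklevel=2,
        )
    if out is not None:
        (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    return summary


def sweep(
    config: ScenarioConfig,
    axis: str,
    values: Sequence[float],
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Mean Ripley z (with 1.96 SE) along an ``m`` or ``theta`` axis."""
    if axis not in ("m", "theta"):
        raise ValueError("axis must be 'm' or 'theta'")
    rows = []
    for v in values:
        cfg = ScenarioConfig(**{**asdict(config), axis: v})
        summ = run_scenario(
            cfg,
            None if out_dir is None else Path(out_dir) / f"{axis}_{v}",
            methods=("ripley",),
        )
        mean_z, ci = summ.mean_z("ripley")
        rows.append(
            {
                axis: v,
                "mean_z_ripley": mean_z,
                "ci95": ci,
                "percent_significant_ripley": summ.percent_significant("ripley"),
                "n": summ.n,
            }
        )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / f"sweep_{axis}.csv", index=False)
    return df


def compcol_ode(
    n_species: int = 201,
    s: float = 0.15,
    mu: float = 1.0,
    t_end: float = 1e6,
    tol: float = 1e-8,
):
    """Deterministic tradeoff equilibrium on the standard fecundity grid."""
    f = fecundity_grid(n_species)
    Gamma = displacement_matrix(f, s)
    N0 = np.full(n_species, 1e-3)
    result = deterministic_dynamics(N0, f, Gamma, mu=mu, t_end=t_end, tol=tol)
    return result, f


def make_fixture(
    kind: str,
    rng: np.random.Generator,
    pool_size: int = 400,
    k: int = 13,
    width: float = 0.005,
    total_abundance: int = 21000,
    theta: float = 50.0,
) -> tuple[Community, RegionalPool]:
    """Synthetic community with a known clustering answer (test surface).

    ``k_clumps``: k equally spaced Gaussian clumps of standard deviation
    ``width`` and equal total abundance on a uniform-trait pool.
    ``single_cluster``: one clump centered at 0.5.  ``uniform``: the same
    abundance multiset shuffled independently of traits (null-calibrated
    by construction).
    """
    traits = rng.uniform(0.0, 1.0, size=pool_size)
    q = np.full(pool_size, 1.0 / pool_size)
    pool = RegionalPool(
        species_id=np.arange(pool_size),
        trait=traits,
        q=q,
        theta=theta,
        metacommunity_size=max(pool_size, total_abundance),
    )
    N = np.zeros(pool_size, dtype=np.int64)
    if kind == "k_clumps" or kind == "single_cluster":
        if kind == "single_cluster":
            centers = np.array([0.5])
        else:
            centers = (np.arange(k) + 0.5) / k
        spacing = 1.0 / max(centers.size, 1)
        if width >= spacing:
            warnings.warn(
                "clump width >= clump spacing: fixture is not separable",
                stacklevel=2,
            )
        per_clump = total_abundance // centers.size
        for c in centers:
            # occupy the pool species nearest to draws from the clump
            draws = rng.normal(c, width, size=per_clump)
            idx = np.abs(traits[None, :] - draws[:, None]).argmin(axis=1)
            np.add.at(N, idx, 1)
    elif kind == "uniform":
        N = rng.multinomial(total_abundance, q).astype(np.int64)
        N = rng.permutation(N)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if N.sum() == 0:
        raise ValueError("fixture produced an empty community")
    return Community(pool, N, m=0.0), pool
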