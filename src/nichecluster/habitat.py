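"""Spatially explicit habitat-gradient lottery.

A line of L sites carries a linear environmental gradient env(a) mapped
onto [0, 1]; each species' trait is its environmental optimum.  All
individuals share the same mortality; when a site is vacated, the local
seed lottery weights each species by its tolerance to the site,
``T_ai = exp[-(Delta_ai / sigma)^2]``, times the dispersal-weighted seed
rain from its current occupants, with Gaussian dispersal
``D_ab = exp[-0.5 (d_ab / d_disp)^2]``.  With probability m the vacancy
goes to an immigrant drawn from the regional pool instead (the printed
recruitment formula applies no tolerance filter to immigrants; a config
flag enables the filtered alternative).  ``d_disp = 1e5`` makes arrival
effectively distance-independent (global dispersal); ``d_disp = 50``
gives local dispersal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .lottery import Community
from .pool import RegionalPool

__all__ = [
    "SpatialCommunity",
    "tolerance",
    "dispersal_kernel",
    "recruit_probabilities",
    "run_spatial",
]


@dataclass
class SpatialCommunity:
    """Occupancy of L gradient sites (every site always occupied)."""

    pool: RegionalPool
    occupant: np.ndarray
    d_disp: float
    sigma: float
    m: float

    def __post_init__(self) -> None:
        self.occupant = np.asarray(self.occupant, dtype=np.int64)
        if np.any(self.occupant < 0) or np.any(self.occupant >= self.pool.S):
            raise ValueError("occupants must be valid pool species indices")
        if self.d_disp <= 0 or self.sigma <= 0:
            raise ValueError("d_disp and sigma must be positive")

    @property
    def L(self) -> int:
        return self.occupant.size

    @property
    def env(self) -> np.ndarray:
        """Linear gradient mapped to [0, 1]: env(a) = a / (L - 1)."""
        L = self.L
        if L == 1:
            return np.zeros(1)
        return np.arange(L) / (L - 1)

    def abundances(self) -> Community:
        """Derived aspatial community (site counts per species)."""
        N = np.bincount(self.occupant, minlength=self.pool.S)
        return Community(self.pool, N.astype(np.int64), self.m)

    def copy(self) -> "SpatialCommunity":
        return SpatialCommunity(
            self.pool, self.occupant.copy(), self.d_disp, self.sigma, self.m
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "site": np.arange(self.L),
                "env": self.env,
                "species_id": self.pool.species_id[self.occupant],
                "trait": self.pool.trait[self.occupant],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def tolerance(env_a, optimum_i, sigma: float):
    """T_ai = exp[-(Delta_ai / sigma)^2]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    delta = np.asarray(env_a, dtype=float) - np.asarray(optimum_i, dtype=float)
    return np.exp(-((delta / sigma) ** 2))


def dispersal_kernel(d_ab, d_disp: float):
    """Gaussian dispersal D_ab = exp[-0.5 (d_ab / d_disp)^2]."""
    if d_disp <= 0:
        raise ValueError("d_disp must be positive")
    d = np.asarray(d_ab, dtype=float)
    return np.exp(-0.5 * (d / d_disp) ** 2)


def recruit_probabilities(
    site_a: int,
    community: SpatialCommunity,
    filter_immigrants: bool = False,
) -> np.ndarray:
    """Probability that each species fills the vacancy at ``site_a``.

    The vacated site contributes no seeds (the sum runs over sites b != a).
    The local term for species i is T_ai * sum over its occupied sites of
    D_ab, normalized over species and scaled by (1 - m); the immigrant term
    is m q_i, or, with ``filter_immigrants``, m times the
    tolerance-weighted renormalized pool.
    """
    pool = community.pool
    L = community.L
    env_a = community.env[site_a]
    T_a = tolerance(env_a, pool.trait, community.sigma)
    sites = np.arange(L)
    D_a = dispersal_kernel(np.abs(sites - site_a), community.d_disp)
    disp = np.zeros(pool.S)
    np.add.at(disp, community.occupant, D_a)
    disp[community.occupant[site_a]] -= D_a[site_a]  # b != a
    local = T_a * disp
    total = local.sum()
    if total <= 0 and community.m == 0:
        raise ValueError("empty local seed rain with no immigration")
    local = local / total if total > 0 else local
    if filter_immigrants:
        imm = T_a * pool.q
        imm = imm / imm.sum()
    else:
        imm = pool.q
    return community.m * imm + (1.0 - community.m) * local


def init_spatial(
    pool: RegionalPool,
    sigma: float,
    d_disp: float,
    m: float,
    L: int,
    rng: np.random.Generator,
) -> SpatialCommunity:
    """Each site initially holds an independent draw from the pool."""
    occupant = rng.choice(pool.S, size=L, p=pool.q)
    return SpatialCommunity(pool, occupant, d_disp, sigma, m)


def run_spatial(
    pool: RegionalPool,
    sigma: float,
    d_disp: float,
    m: float,
    generations: float,
    seed: int,
    L: int = 1000,
    snapshot_every: float | None = None,
) -> list[SpatialCommunity]:
    """Run the habitat lottery; one generation is L death/recruitment
    events.  Returns snapshots (copies) plus the final state."""
    ss = np.random.SeedSequence(seed)
    init_seed, loop_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    community = init_spatial(
        pool, sigma, d_disp, m, L, np.random.default_rng(init_seed)
    )
    env = community.env
    T = tolerance(env[:, None], pool.trait[None, :], sigma)
    D_table = dispersal_kernel(np.arange(L, dtype=float), d_disp)
    imm_cdf = np.cumsum(pool.q)
    imm_cdf[-1] = 1.0
    n_events = int(round(generations * L))
    every = (
        n_events
        if snapshot_every is None
        else max(1, int(round(snapshot_every * L)))
    )
    out: list[SpatialCommunity] = []
    done = 0
    first = True
    while done < n_events:
        chunk = min(every, n_events - done)
        _kernels.simulate_habitat(
            community.occupant,
            T,
            D_table,
            imm_cdf,
            float(m),
            chunk,
            loop_seed,
            first,
        )
        first = False
        done += chunk
        out.append(community.copy())
    return out
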