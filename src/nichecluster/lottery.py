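"""Zero-sum lottery scheduler shared by all aspatial community models.

Every model is expressed as a :class:`ModelRule` giving non-negative
per-species weights for death, local recruitment and immigrant recruitment.
An event removes one individual (species drawn proportionally to the death
weights) and immediately recruits one: with probability ``m`` an immigrant
(weights default to the regional relative abundances ``q``), otherwise a
local birth.  Recruitment weights are evaluated on the post-death state, so
the community size ``J`` is invariant.

This module is the readable, reference implementation used for testing and
small communities; the production-scale simulators in ``_kernels`` run the
same event scheme in compiled loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .pool import RegionalPool

__all__ = [
    "Community",
    "ModelRule",
    "neutral_rule",
    "step_event",
    "run",
    "stationarity_diagnostic",
    "init_community",
]


@dataclass
class Community:
    """Local community: abundances over pool species with fixed total J."""

    pool: RegionalPool
    N: np.ndarray
    m: float
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=np.int64)
        if self.N.size != self.pool.S:
            raise ValueError("abundance vector must be indexed by pool species")
        if np.any(self.N < 0):
            raise ValueError("abundances must be non-negative")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("immigration rate m must be in [0, 1]")

    @property
    def J(self) -> int:
        return int(self.N.sum())

    @property
    def richness(self) -> int:
        return int(np.count_nonzero(self.N))

    def copy(self) -> "Community":
        return Community(self.pool, self.N.copy(), self.m, dict(self.aux))

    def to_frame(self) -> pd.DataFrame:
        """Community table with zero-abundance species omitted."""
        keep = self.N > 0
        return pd.DataFrame(
            {
                "species_id": self.pool.species_id[keep],
                "trait": self.pool.trait[keep],
                "abundance": self.N[keep],
            }
        )

    def save(self, path: str | Path, metadata: Optional[dict] = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            path.with_suffix(".json").write_text(json.dumps(metadata, indent=1))


@dataclass
class ModelRule:
    """Per-model weight functions consumed by the lottery scheduler.

    Each callable maps the current :class:`Community` to a non-negative,
    finite weight vector over pool species.  ``recruit_immigrant_weights``
    defaults to the regional relative abundances.  ``post_event_hook`` (used
    by the consumer-resource model) runs after each death/recruitment pair
    and may mutate auxiliary state.
    """

    death_weights: Callable[[Community], np.ndarray]
    recruit_local_weights: Callable[[Community], np.ndarray]
    recruit_immigrant_weights: Optional[Callable[[RegionalPool], np.ndarray]] = None
    post_event_hook: Optional[Callable[[Community, np.random.Generator], None]] = None

    def immigrant_weights(self, pool: RegionalPool) -> np.ndarray:
        if self.recruit_immigrant_weights is None:
            return pool.q
        return np.asarray(self.recruit_immigrant_weights(pool), dtype=float)


def neutral_rule() -> ModelRule:
    """All individuals equivalent: death and local birth both per capita."""
    return ModelRule(
        death_weights=lambda c: c.N.astype(float),
        recruit_local_weights=lambda c: c.N.astype(float),
    )


def _sample(weights: np.ndarray, rng: np.random.Generator, what: str) -> int:
    weights = np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(weights)):
        raise RuntimeError(f"non-finite {what} weights (model bug)")
    if np.any(weights < 0):
        raise RuntimeError(f"negative {what} weights (model bug)")
    total = weights.sum()
    if total <= 0.0:
        raise RuntimeError(f"degenerate model: all {what} weights are zero")
    return int(rng.choice(weights.size, p=weights / total))


def step_event(
    community: Community, rule: ModelRule, rng: np.random.Generator
) -> Community:
    """One death/recruitment pair, in place.  Returns the community."""
    if community.J < 1:
        raise ValueError("cannot step an empty community")
    dead = _sample(rule.death_weights(community), rng, "death")
    community.N[dead] -= 1
    if rng.random() < community.m:
        recruit = _sample(
            rule.immigrant_weights(community.pool), rng, "immigrant recruitment"
        )
    else:
        recruit = _sample(
            rule.recruit_local_weights(community), rng, "local recruitment"
        )
    community.N[recruit] += 1
    if rule.post_event_hook is not None:
        rule.post_event_hook(community, rng)
    return community


def run(
    community: Community,
    rule: ModelRule,
    generations: float,
    rng: np.random.Generator,
    snapshot_every: Optional[float] = None,
) -> list[Community]:
    """Advance ``round(generations * J)`` events; one generation is J events.

    Returns the requested snapshots (copies) plus the final state.  The
    input community is advanced in place.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    J = community.J
    n_events = int(round(generations * J))
    every = None if snapshot_every is None else max(1, int(round(snapshot_every * J)))
    snapshots: list[Community] = []
    for e in range(1, n_events + 1):
        step_event(community, rule, rng)
        if every is not None and e % every == 0 and e < n_events:
            snapshots.append(community.copy())
    snapshots.append(community.copy())
    return snapshots


def init_community(
    pool: RegionalPool, J: int, m: float, rng: np.random.Generator
) -> Community:
    """Initial community: J individuals drawn from the pool proportionally
    to regional relative abundance (a random draw of offspring)."""
    if J < 1:
        raise ValueError("J must be >= 1")
    N = rng.multinomial(J, pool.q)
    return Community(pool, N.astype(np.int64), m)


def stationarity_diagnostic(snapshots: Sequence[Community]) -> pd.DataFrame:
    """Per-snapshot richness, Shannon diversity and total-variation distance
    of relative abundances from the previous snapshot.

    Purely descriptive: burn-in adequacy is judged by the caller.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots")
    rows = []
    prev = None
    for t, snap in enumerate(snapshots):
        p = snap.N / snap.N.sum()
        pos = p[p > 0]
        shannon = float(-(pos * np.log(pos)).sum())
        tv = np.nan if prev is None else 0.5 * float(np.abs(p - prev).sum())
        rows.append(
            {
                "snapshot": t,
                "richness": snap.richness,
                "shannon": shannon,
                "tv_distance": tv,
            }
        )
        prev = p
    return pd.DataFrame(rows)
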