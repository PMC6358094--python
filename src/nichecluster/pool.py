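"""Regional species pool: a fixed neutral metacommunity supplying immigrants.

The pool is assembled once by Hubbell's sequential neutral rule with
biodiversity parameter ``theta`` and then frozen: local communities draw
immigrants from it in proportion to regional relative abundance ``q`` but
never feed back into it.  Each species carries a trait on [0, 1] which, in
the niche models, doubles as its position on the niche axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

__all__ = ["RegionalPool", "generate_pool", "expected_richness"]


@dataclass(frozen=True)
class RegionalPool:
    """Immutable regional metacommunity.

    Attributes
    ----------
    species_id : ndarray of int
        Species labels, assigned in order of founding during assembly.
    trait : ndarray of float
        Trait values on the closed interval [0, 1].
    q : ndarray of float
        Regional relative abundances; strictly positive, summing to 1.
    theta : float
        Biodiversity parameter of the neutral assembly.
    metacommunity_size : int
        Number of individuals in the assembled metacommunity.
    seed : int or None
        Seed used for assembly, if known.
    """

    species_id: np.ndarray
    trait: np.ndarray
    q: np.ndarray
    theta: float
    metacommunity_size: int
    seed: int | None = None
    fecundity: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("species_id", "trait", "q"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.trait.min(initial=1.0) < 0.0 or self.trait.max(initial=0.0) > 1.0:
            raise ValueError("traits must lie in [0, 1]")
        if np.any(self.q <= 0):
            raise ValueError("all regional relative abundances must be positive")
        if abs(self.q.sum() - 1.0) > 1e-12:
            raise ValueError("regional relative abundances must sum to 1")
        if not (1 <= self.S <= self.metacommunity_size):
            raise ValueError("species count must be in [1, metacommunity_size]")

    @property
    def S(self) -> int:
        """Number of species in the pool."""
        return self.trait.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species_id": self.species_id, "trait": self.trait, "q": self.q}
        )

    def save(self, path: str | Path) -> None:
        """Write the pool as CSV plus a JSON sidecar with assembly metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "theta": self.theta,
            "metacommunity_size": self.metacommunity_size,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RegionalPool":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            species_id=df["species_id"].to_numpy(),
            trait=df["trait"].to_numpy(float),
            q=df["q"].to_numpy(float),
            theta=float(meta.get("theta", np.nan)),
            metacommunity_size=int(meta.get("metacommunity_size", df.shape[0])),
            seed=meta.get("seed"),
        )


@njit(cache=True)
def _neutral_assembly(theta: float, size: int, seed: int) -> np.ndarray:
    """Sequential neutral assembly (Hoppe urn): individual i+1 founds a new
    species with probability theta/(theta+i), else copies a uniform-random
    existing individual.  Returns per-species abundance counts."""
    np.random.seed(seed)
    counts = np.zeros(size, dtype=np.int64)
    species_of = np.empty(size, dtype=np.int64)
    n_species = 0
    for i in range(size):
        if np.random.random() < theta / (theta + i):
            species_of[i] = n_species
            counts[n_species] = 1
            n_species += 1
        else:
            sp = species_of[np.random.randint(0, i)]
            species_of[i] = sp
            counts[sp] += 1
    return counts[:n_species]


def _check_params(theta: float, metacommunity_size: int) -> None:
    if theta <= 0:
        raise ValueError("theta must be positive")
    if metacommunity_size < 1:
        raise ValueError("metacommunity_size must be >= 1")


def generate_pool(theta: float, metacommunity_size: int, seed: int) -> RegionalPool:
    """Assemble a neutral metacommunity and attach i.i.d. uniform traits.

    Traits are drawn independently of abundance: the pool itself carries no
    trait structure, so any trait-abundance association in a local community
    is produced by the local dynamics.
    """
    _check_params(theta, metacommunity_size)
    ss = np.random.SeedSequence(seed)
    assembly_seed, trait_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    counts = _neutral_assembly(float(theta), int(metacommunity_size), assembly_seed)
    rng = np.random.default_rng(trait_seed)
    traits = rng.uniform(0.0, 1.0, size=counts.size)
    return RegionalPool(
        species_id=np.arange(counts.size),
        trait=traits,
        q=counts / counts.sum(),
        theta=float(theta),
        metacommunity_size=int(metacommunity_size),
        seed=int(seed),
    )


def expected_richness(theta: float, metacommunity_size: int) -> float:
    """Exact expected species count of the neutral assembly.

    Each individual i = 0..J_M-1 founds a new species independently with
    probability theta/(theta+i), so the expectation is the sum of those
    probabilities.
    """
    _check_params(theta, metacommunity_size)
    i = np.arange(metacommunity_size, dtype=float)
    return float(np.sum(theta / (theta + i)))
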