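"""Consumer-resource lottery with explicit stochastic resource dynamics.

Resources live on the same [0, 1] axis as consumer traits; consumer i's
preference for resource a is ``C_ai = exp[-(d_ai / sigma)^2]`` with d_ai
the distance between the resource position and the consumer's preferred
resource (its trait).  Consumers die per capita and recruit in proportion
to their harvest ``sum_a C_ai X_a N_i``.  Resources follow their own
birth-death process: consumption kills (weight ``sum_i C_ai X_a N_i``),
logistic growth gives birth (weight ``(1 - X_a/K) X_a``), and a resource
depleted to zero is extirpated for good — there is no resource
immigration.  The carrying capacity K controls depletion: at K = 100
depletion is mild and dynamics approach a Gaussian-kernel Lotka-Volterra
limit; at K = 400 extirpations carve gaps in the resource continuum that
consumers then cluster around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .lottery import Community, init_community
from .pool import RegionalPool

__all__ = [
    "ResourceState",
    "ResourceParams",
    "preference_matrix",
    "consumer_weights",
    "resource_weights",
    "run_coupled",
]


@dataclass
class ResourceState:
    """Positions and integer abundances of the sampled resource continuum."""

    y: np.ndarray
    X: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=np.int64)
        if np.any(self.X < 0):
            raise ValueError("resource abundances must be non-negative")
        if self.K < 1:
            raise ValueError("carrying capacity K must be >= 1")

    @property
    def extirpated(self) -> np.ndarray:
        return self.X == 0

    def copy(self) -> "ResourceState":
        return ResourceState(self.y.copy(), self.X.copy(), self.K)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"resource_pos": self.y, "abundance": self.X})

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ResourceParams:
    """sigma: preference width; K: carrying capacity; n_resources: initial
    number of resources (positions uniform on [0,1]); rho: resource
    death/birth pairs interleaved per consumer event pair; X0: initial
    abundance of every resource.

    X0 is deliberately independent of K: the paired death/birth scheme
    conserves total resource abundance, so equal X0 gives both depletion
    scenarios the same initial resource supply, and the ceiling K alone
    determines how unevenly that supply can concentrate.  A high ceiling
    (K = 400) lets abundance pile onto few favoured resources while the
    rest are extirpated (severe depletion); a low ceiling (K = 100) pins
    resources near their logistic ceiling, suppressing fluctuations and
    extirpation (mild depletion).
    """

    sigma: float = 0.03
    K: int = 400
    n_resources: int = 500
    rho: int = 1
    X0: int = 50

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.K < 1 or self.n_resources < 1 or self.rho < 1:
            raise ValueError("K, n_resources and rho must be >= 1")
        if not 1 <= self.X0 <= self.K:
            raise ValueError("initial abundance X0 must be in [1, K]")


def preference_matrix(y: np.ndarray, x: np.ndarray, sigma: float) -> np.ndarray:
    """C_ai = exp[-(d_ai / sigma)^2], shape (n_resources, S)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    d = np.abs(y[:, None] - x[None, :])
    return np.exp(-((d / sigma) ** 2))


def consumer_weights(
    N: np.ndarray, X: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(death, local recruitment) weights for consumers.

    Death is per capita (equal mortality); recruitment of species i is
    proportional to its total harvest sum_a C_ai X_a N_i.
    """
    N = np.asarray(N, dtype=float)
    X = np.asarray(X, dtype=float)
    if C.shape != (X.size, N.size):
        raise ValueError("preference matrix shape mismatch")
    return N.copy(), N * (C.T @ X)


def resource_weights(
    N: np.ndarray, X: np.ndarray, C: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """(death, birth) weights for resources.

    Death of resource a is proportional to its consumption
    X_a sum_i C_ai N_i; birth to logistic growth (1 - X_a/K) X_a, clamped
    at zero above the ceiling.  Both vanish at X_a = 0, making extirpation
    absorbing.
    """
    N = np.asarray(N, dtype=float)
    X = np.asarray(X, dtype=float)
    death = X * (C @ N)
    birth = np.maximum(0.0, 1.0 - X / K) * X
    return death, birth


def init_resources(
    params: ResourceParams, rng: np.random.Generator
) -> ResourceState:
    """Uniform-random positions; every resource starts at abundance X0."""
    y = np.sort(rng.uniform(0.0, 1.0, size=params.n_resources))
    X = np.full(params.n_resources, params.X0, dtype=np.int64)
    return ResourceState(y, X, params.K)


def run_coupled(
    pool: RegionalPool,
    params: ResourceParams,
    J: int,
    m: float,
    generations: float,
    seed: int,
    snapshot_every: float | None = None,
) -> list[tuple[Community, ResourceState]]:
    """Run the coupled consumer-resource process; one generation is J
    consumer event pairs, each followed by ``rho`` resource pairs.

    Returns snapshots (copies) plus the final state.
    """
    ss = np.random.SeedSequence(seed)
    init_seed, res_seed, loop_seed = (
        int(s) for s in ss.generate_state(3) % (2**31)
    )
    rng = np.random.default_rng(init_seed)
    community = init_community(pool, J, m, rng)
    resources = init_resources(params, np.random.default_rng(res_seed))
    C = preference_matrix(resources.y, pool.trait, params.sigma)
    imm_cdf = np.cumsum(pool.q)
    imm_cdf[-1] = 1.0
    n_events = int(round(generations * J))
    every = (
        n_events
        if snapshot_every is None
        else max(1, int(round(snapshot_every * J)))
    )
    out: list[tuple[Community, ResourceState]] = []
    done = 0
    first = True
    while done < n_events:
        chunk = min(every, n_events - done)
        _kernels.simulate_resource(
            community.N,
            resources.X,
            C,
            float(params.K),
            params.rho,
            float(m),
            imm_cdf,
            chunk,
            loop_seed,
            first,
        )
        first = False
        done += chunk
        out.append((community.copy(), resources.copy()))
    return out
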