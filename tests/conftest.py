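import numpy as np
import pytest

from nichecluster import RegionalPool, generate_pool


@pytest.fixture(scope="session")
def small_pool() -> RegionalPool:
    """A small assembled pool (theta=5, 500 individuals)."""
    return generate_pool(theta=5.0, metacommunity_size=500, seed=123)


@pytest.fixture(scope="session")
def toy_pool() -> RegionalPool:
    """Hand-built 4-species pool with known traits and frequencies."""
    return RegionalPool(
        species_id=np.arange(4),
        trait=np.array([0.1, 0.4, 0.6, 0.9]),
        q=np.array([0.4, 0.3, 0.2, 0.1]),
        theta=1.0,
        metacommunity_size=10,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
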