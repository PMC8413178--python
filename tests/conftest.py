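import numpy as np
import pytest

from mvcbt import MultiViewPopulation, SyntheticConfig, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng, n, nonneg=True):
    x = rng.random((n, n)) if nonneg else rng.standard_normal((n, n))
    x = (x + x.T) / 2.0
    np.fill_diagonal(x, 0.0)
    return x


@pytest.fixture
def small_population(rng):
    """5 subjects x 2 views x 6 ROIs of valid random networks."""
    nets = np.stack(
        [[random_symmetric(rng, 6) for _ in range(2)] for _ in range(5)]
    )
    return MultiViewPopulation(networks=nets)


@pytest.fixture
def clustered_population():
    """Well-separated 3-cluster synthetic population (seeded)."""
    cfg = SyntheticConfig(n_subjects=30, n_views=2, n_rois=12, n_clusters=3, seed=7)
    return simulate_population(cfg)
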