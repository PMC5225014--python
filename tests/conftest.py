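import numpy as np
import pytest

from weanling import SimConfig, simulate
from weanling.datatypes import DistanceMatrix


@pytest.fixture(scope="session")
def small_config():
    """Trimmed generator settings so session fixtures stay fast."""
    return SimConfig(seed=11, n_otus=60, n_discriminant=10)


@pytest.fixture(scope="session")
def study(small_config):
    return simulate.simulate_study(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distance_matrix(rng, n, labels=None):
    """Symmetric i.i.d.-uniform dissimilarities with zero diagonal."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = rng.uniform(size=iu[0].size)
    m = m + m.T
    return DistanceMatrix(labels=labels or [f"s{i}" for i in range(n)], values=m)
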