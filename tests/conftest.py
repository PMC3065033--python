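import numpy as np
import pytest

from neurosync import WeightedNetwork, gen_random_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    """Unit-weight binary triangle."""
    W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
    return WeightedNetwork(W, mode="binary")


@pytest.fixture
def path3():
    """Binary path graph 1-2-3."""
    W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    return WeightedNetwork(W, mode="binary")


@pytest.fixture
def star11():
    """Star: vertex 0 is the hub, 10 leaves, unit weights."""
    W = np.zeros((11, 11))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    return WeightedNetwork(W, mode="binary")


def random_sync_matrix(rng, n, density=0.5):
    """Random symmetric synchronization matrix with values in [0, 1]."""
    vals = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    M = np.where(mask, vals, 0.0)
    M = np.triu(M, k=1)
    M = M + M.T
    return M


@pytest.fixture
def small_nets():
    """A deterministic batch of small random greyscale networks."""
    return [
        gen_random_network(n, density, seed=seed)
        for seed, (n, density) in enumerate(
            [(4, 0.6), (5, 0.5), (6, 0.5), (7, 0.4), (8, 0.35), (6, 0.9), (5, 1.0)]
        )
    ]
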