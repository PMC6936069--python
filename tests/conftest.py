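import numpy as np
import pytest

from brainnetmf import WeightedNetwork


def random_symmetric_nonneg(rng, n, scale=1.0):
    """Random symmetric nonnegative matrix with zero diagonal."""
    a = rng.uniform(0.0, scale, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles on nodes 0-2 and 3-5."""
    w = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        w[a, b] = w[b, a] = 1.0
    return WeightedNetwork([str(i) for i in range(6)], w)


@pytest.fixture
def four_cycle():
    """Unit-weight cycle 0-1-2-3-0."""
    w = np.zeros((4, 4))
    for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
        w[a, b] = w[b, a] = 1.0
    return WeightedNetwork([str(i) for i in range(4)], w)


@pytest.fixture
def block_diagonal_pair():
    """6-node matrix with two dense 3-node blocks of weight 0.7."""
    w = np.zeros((6, 6))
    w[:3, :3] = 0.7
    w[3:, 3:] = 0.7
    np.fill_diagonal(w, 0.0)
    return w
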