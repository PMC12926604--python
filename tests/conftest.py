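import numpy as np
import pytest

from fcgraph.connectivity import Network


def make_net(adj, scheme="absolute", threshold=0.5, labels=None):
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    return Network(
        adjacency=adj,
        scheme=scheme,
        threshold=None if scheme == "weighted" else threshold,
        region_labels=labels or [f"n{i}" for i in range(n)],
    )


def random_binary_adj(rng, n, p):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, 1)
    return a + a.T


def random_weighted_adj(rng, n, p):
    a = random_binary_adj(rng, n, p)
    w = np.triu(rng.uniform(0.05, 1.0, (n, n)), 1) * np.triu(a, 1)
    return w + w.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k4():
    a = np.ones((4, 4)) - np.eye(4)
    return make_net(a)


@pytest.fixture
def star4():
    """Hub node 0 with three leaves."""
    a = np.zeros((4, 4))
    a[0, 1:] = 1
    a[1:, 0] = 1
    return make_net(a)


@pytest.fixture
def path3():
    a = np.zeros((3, 3))
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return make_net(a)


@pytest.fixture
def two_triangles():
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1
    return make_net(a)
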