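import numpy as np
import pytest

from connwalk import ConnectivityMatrix, build_model


def graph_from_edges(n, edges):
    C = np.zeros((n, n))
    for a, b, *w in edges:
        C[a, b] = C[b, a] = w[0] if w else 1.0
    return ConnectivityMatrix(C)


def random_connectivity(n, rng, density=0.5, allow_isolated=True):
    """Random symmetric weighted graph; may contain isolated nodes."""
    while True:
        mask = np.triu(rng.random((n, n)) < density, k=1)
        if mask.sum() >= 1:
            break
    W = np.where(mask, rng.random((n, n)), 0.0)
    if not allow_isolated:
        deg = (W + W.T > 0).sum(axis=1)
        for i in np.flatnonzero(deg == 0):
            j = (i + 1) % n
            W[min(i, j), max(i, j)] = rng.random() + 1e-6
    return ConnectivityMatrix(W + W.T)


@pytest.fixture
def cycle4():
    """4-node unit-weight cycle: the canonical worked toy graph."""
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def cycle4_model(cycle4):
    return build_model(cycle4)


@pytest.fixture
def path3():
    """3-node path with unit weights: mu = (1/4, 1/2, 1/4)."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def path3_model(path3):
    return build_model(path3)


@pytest.fixture
def star5():
    """Star: center node 0 with 4 unit-weight leaves."""
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])
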