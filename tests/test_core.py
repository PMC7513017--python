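import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connwalk import ConnectivityMatrix, build_model, symmetrize

from conftest import graph_from_edges, random_connectivity


class TestConnectivityMatrix:
    def test_rejects_negative_weight(self):
        C = np.array([[0.0, -0.3], [-0.3, 0.0]])
        with pytest.raises(ValueError, match=r"negative weight C\[0,1\]"):
            ConnectivityMatrix(C)

    def test_rejects_asymmetric(self):
        C = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            ConnectivityMatrix(C)

    def test_rejects_self_loop(self):
        C = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="self-loops"):
            ConnectivityMatrix(C)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            ConnectivityMatrix(np.zeros((2, 3)))

    def test_edge_count_and_density(self, cycle4):
        assert cycle4.n_edges == 4
        assert cycle4.density == pytest.approx(4 / 6)


class TestSymmetrize:
    def test_copies_upper_triangle(self):
        M = np.zeros((3, 3))
        M[0, 1] = 0.7
        C = symmetrize(M)
        assert C.C[0, 1] == C.C[1, 0] == 0.7

    def test_zeroes_diagonal(self):
        M = np.eye(3) + np.ones((3, 3))
        C = symmetrize(M)
        assert np.all(np.diagonal(C.C) == 0)

    def test_idempotent_on_symmetric_input(self):
        M = np.array([[0, 2.0, 0], [2.0, 0, 1.0], [0, 1.0, 0]])
        assert np.array_equal(symmetrize(M).C, M)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            symmetrize(np.zeros((2, 3)))


class TestBuildModel:
    def test_cycle_uniform_stationary(self, cycle4_model):
        assert np.allclose(cycle4_model.mu, 0.25)
        for i in range(4):
            row = cycle4_model.P[i]
            assert sorted(row[row > 0]) == [0.5, 0.5]

    def test_single_edge_any_weight(self):
        for w in (1.0, 0.01, 37.5):
            m = build_model(graph_from_edges(2, [(0, 1, w)]))
            assert np.allclose(m.mu, [0.5, 0.5])
            assert np.array_equal(m.P, [[0, 1], [1, 0]])

    def test_path3_hand_enumerated(self, path3_model):
        # strengths (1, 2, 1), C_T = 4
        assert np.allclose(path3_model.strengths, [1, 2, 1])
        assert path3_model.C_T == 4.0
        assert np.allclose(path3_model.mu, [0.25, 0.5, 0.25])
        assert np.allclose(path3_model.P[1], [0.5, 0, 0.5])

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError, match="no edges"):
            build_model(ConnectivityMatrix(np.zeros((3, 3))))

    def test_isolated_node_zero_row_zero_mass(self):
        m = build_model(graph_from_edges(3, [(0, 1)]))
        assert m.mu[2] == 0.0
        assert np.all(m.P[2] == 0.0)
        assert m.isolated.tolist() == [False, False, True]
        m.validate()

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        m = build_model(random_connectivity(rng.integers(2, 30), rng))
        m.validate()  # stochastic rows, normalized mu, detailed balance

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1e6])
    def test_scale_invariance(self, path3, scale):
        base = build_model(path3)
        scaled = build_model(ConnectivityMatrix(path3.C * scale))
        assert np.allclose(scaled.P, base.P, atol=1e-12)
        assert np.allclose(scaled.mu, base.mu, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_stationarity_mu_is_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        m = build_model(random_connectivity(int(rng.integers(2, 16)), rng))
        assert np.allclose(m.mu @ m.P, m.mu, atol=1e-12)

    def test_locality_of_stationary_distribution(self):
        # redistributing weight among edges not touching node 0, with C_T
        # fixed, leaves mu_0 unchanged
        rng = np.random.default_rng(42)
        C = random_connectivity(8, rng, density=0.8).C.copy()
        mu0 = build_model(ConnectivityMatrix(C)).mu[0]
        # move weight between two edges that avoid node 0
        pairs = [(i, j) for i in range(1, 8) for j in range(i + 1, 8) if C[i, j] > 0]
        (a, b), (c, d) = pairs[0], pairs[1]
        delta = 0.5 * C[a, b]
        C[a, b] -= delta; C[b, a] -= delta
        C[c, d] += delta; C[d, c] += delta
        assert build_model(ConnectivityMatrix(C)).mu[0] == pytest.approx(mu0, abs=1e-12)
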