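import numpy as np
import pytest

from connwalk import (
    build_model,
    compute_global,
    compute_local,
    entropic_surprise,
    erasure_surprise,
    mutual_predictability,
    mutual_surprise,
)

import oracles
from conftest import graph_from_edges, random_connectivity


class TestWorkedToyGraphs:
    def test_cycle4_every_node_identical(self, cycle4_model):
        table = compute_local(cycle4_model)
        assert np.allclose(table["E"], 2.0, atol=1e-12)
        assert np.allclose(table["I1"], 1.0, atol=1e-12)
        assert np.allclose(table["I2"], 1.0, atol=1e-12)
        assert np.allclose(table["I1e"], 1.0, atol=1e-12)

    def test_single_edge_surprise_uniform(self):
        m = build_model(graph_from_edges(2, [(0, 1)]))
        assert np.allclose(entropic_surprise(m), [1.0, 1.0])

    def test_path3_hand_derived(self, path3_model):
        # mu = (1/4, 1/2, 1/4): E = (2, 1, 2); per-row KL gives I1 = 1 each;
        # row entropies (0, 1, 0) subtracted from H = 1.5 give I2; triple
        # enumeration gives I1e = 1 each
        table = compute_local(path3_model)
        assert np.allclose(table["E"], [2, 1, 2], atol=1e-12)
        assert np.allclose(table["I1"], [1, 1, 1], atol=1e-12)
        assert np.allclose(table["I2"], [1.5, 0.5, 1.5], atol=1e-12)
        assert np.allclose(table["I1e"], [1, 1, 1], atol=1e-12)

    def test_star_graph_kl_values(self, star5):
        m = build_model(star5)
        I1 = mutual_surprise(m)
        # leaves jump to the center with certainty: log2(1 / (1/2)) = 1 bit;
        # the center spreads over 4 leaves of mass 1/8: log2(2) = 1 bit
        assert np.allclose(I1, 1.0, atol=1e-12)
        g = compute_global(m)
        assert float(m.mu @ I1) == pytest.approx(g.MI, abs=1e-9)

    def test_uniform_row_in_uniform_graph_has_zero_predictability(self):
        # complete graph with a self-less uniform row: H(Xt+1 | xi) = H(mu)
        n = 6
        C = np.ones((n, n)) - np.eye(n)
        from connwalk import ConnectivityMatrix

        m = build_model(ConnectivityMatrix(C))
        I2 = mutual_predictability(m)
        expected = np.log2(n) - np.log2(n - 1)
        assert np.allclose(I2, expected, atol=1e-12)


class TestIsolatedNodes:
    def test_isolated_nodes_flagged_not_a_number(self):
        m = build_model(graph_from_edges(4, [(0, 1)]))
        table = compute_local(m)
        assert table.iloc[2:][["E", "I1", "I2", "I1e"]].isna().all().all()
        assert table.iloc[:2].notna().all().all()


class TestDecompositionIdentities:
    @pytest.mark.parametrize("seed", range(25))
    def test_weighted_sums_recover_global_measures(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 65))
        m = build_model(random_connectivity(n, rng, density=float(rng.uniform(0.1, 1.0))))
        g = compute_global(m)
        mu = m.mu
        table = compute_local(m).fillna(0.0)
        assert float(mu @ table["E"]) == pytest.approx(g.H, abs=1e-9)
        assert float(mu @ table["I1"]) == pytest.approx(g.MI, abs=1e-9)
        assert float(mu @ table["I2"]) == pytest.approx(g.MI, abs=1e-9)
        assert float(mu @ table["I1e"]) == pytest.approx(g.EMI, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_nonnegativity_of_surprise_measures(self, seed):
        rng = np.random.default_rng(seed + 100)
        m = build_model(random_connectivity(int(rng.integers(2, 65)), rng))
        connected = ~m.isolated
        assert np.all(entropic_surprise(m)[connected] >= -1e-12)
        assert np.all(mutual_surprise(m)[connected] >= -1e-12)
        assert np.all(erasure_surprise(m)[connected] >= -1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_joint_distribution_enumeration(self, seed):
        rng = np.random.default_rng(seed + 7)
        n = int(rng.integers(2, 9))
        C = random_connectivity(n, rng, density=float(rng.uniform(0.2, 1.0)))
        m = build_model(C)
        want = oracles.local_measures(C.C)
        got = compute_local(m)
        for key in ("E", "I1", "I2", "I1e"):
            np.testing.assert_allclose(got[key].to_numpy(), want[key], atol=1e-9,
                                       err_msg=key, equal_nan=True)


class TestBridgeNodes:
    def test_bridge_between_cliques_has_highest_erasure_surprise(self):
        # two 4-cliques joined only through a bridge node wired to two
        # nodes of each clique; the bridge carries unique paths
        edges = []
        for block in (range(0, 4), range(5, 9)):
            block = list(block)
            edges += [(a, b) for ai, a in enumerate(block) for b in block[ai + 1:]]
        edges += [(4, 2), (4, 3), (4, 5), (4, 6)]
        m = build_model(graph_from_edges(9, edges))
        I1e = erasure_surprise(m)
        # among nodes of equal strength, the bridge scores strictly higher
        same_strength = [i for i in range(9) if i != 4 and m.strengths[i] == m.strengths[4]]
        assert same_strength
        assert all(I1e[4] > I1e[i] for i in same_strength)
        # agrees with the triple-enumeration oracle
        want = oracles.local_measures(m.connectivity.C)["I1e"]
        np.testing.assert_allclose(I1e, want, atol=1e-9)
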