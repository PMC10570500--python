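import numpy as np
import pytest

from richnet import (
    FCMatrix, characteristic_path_length, clustering_coefficients, global_efficiency,
    nodal_metrics, rewire_null, shortest_path_lengths, small_worldness,
)
from conftest import random_fc
from _oracles import (
    betweenness_by_enumeration, clustering_triple_sum, floyd_warshall, random_graph,
)


def path_graph(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


class TestShortestPaths:
    def test_binary_chain(self):
        d = shortest_path_lengths(path_graph(4), mode="binary")
        assert d[0, 3] == 3

    def test_disconnected_dyads_are_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        d = shortest_path_lengths(w, mode="binary")
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_weighted_distances_match_floyd_warshall(self, rng):
        for _ in range(30):
            w = random_graph(rng, n_max=8, weighted=True)
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), 0.0)
            np.testing.assert_allclose(
                shortest_path_lengths(w, "weighted"), floyd_warshall(lengths), atol=1e-12
            )


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        w = 1.0 - np.eye(4)
        assert global_efficiency(w, "binary") == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(np.zeros((5, 5)), "binary") == 0.0

    def test_path_graph_hand_sum(self):
        # P4 pairs: three at d=1, two at d=2, one at d=3
        expected = (3 * 1 + 2 * 0.5 + 1 / 3) / 6
        assert global_efficiency(path_graph(4), "binary") == pytest.approx(expected, abs=1e-12)

    def test_adding_an_edge_never_decreases_efficiency(self, rng):
        for _ in range(20):
            w = random_graph(rng, n_max=7, weighted=False)
            e0 = global_efficiency(w, "binary")
            zeros = np.argwhere(np.triu(w == 0, 1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = 1.0
            assert global_efficiency(w2, "binary") >= e0 - 1e-12


class TestNodalMetrics:
    def test_star_betweenness(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        nm = nodal_metrics(w, "binary")
        assert nm.betweenness[0] == pytest.approx(6.0)   # C(4,2) leaf pairs
        assert np.all(nm.betweenness[1:] == 0)

    def test_isolated_node(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        nm = nodal_metrics(w, "weighted")
        assert nm.degree[2] == 0 and nm.efficiency[2] == 0 and nm.strength[2] == 0

    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_betweenness_matches_path_enumeration(self, mode, rng):
        for _ in range(25):
            w = random_graph(rng, n_max=7, weighted=(mode == "weighted"))
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), 0.0) \
                if mode == "weighted" else (w > 0).astype(float)
            np.testing.assert_allclose(
                nodal_metrics(w, mode).betweenness,
                betweenness_by_enumeration(lengths), atol=1e-9
            )

    def test_permutation_equivariance(self, rng):
        w = random_graph(rng, n_max=8, weighted=True)
        perm = rng.permutation(w.shape[0])
        wp = w[np.ix_(perm, perm)]
        nm = nodal_metrics(w, "weighted")
        nmp = nodal_metrics(wp, "weighted")
        np.testing.assert_allclose(nmp.strength, nm.strength[perm], atol=1e-12)
        np.testing.assert_allclose(nmp.betweenness, nm.betweenness[perm], atol=1e-9)


class TestClustering:
    def test_binary_triangle_is_one(self):
        w = 1.0 - np.eye(3)
        np.testing.assert_allclose(clustering_coefficients(w, "binary"), 1.0)

    def test_binary_star_is_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1.0
        np.testing.assert_allclose(clustering_coefficients(w, "binary"), 0.0)

    @pytest.mark.parametrize("mode", ["binary", "weighted"])
    def test_matches_triple_sum_oracle(self, mode, rng):
        for _ in range(20):
            w = random_graph(rng, n_max=6, weighted=True)
            np.testing.assert_allclose(
                clustering_coefficients(w, mode), clustering_triple_sum(w, mode),
                atol=1e-12,
            )


class TestRewireNull:
    def test_degree_sequence_and_weight_preserved(self, rng):
        for seed in range(10):
            fc = random_fc(rng, n=15, density=0.35)
            null = rewire_null(fc, n_swaps_per_edge=10, seed=seed)
            np.testing.assert_array_equal(
                (null.w > 0).sum(axis=1), (fc.w > 0).sum(axis=1)
            )
            assert null.overall_strength == pytest.approx(fc.overall_strength, abs=1e-12)
            assert sorted(null.w[null.w > 0]) == pytest.approx(sorted(fc.w[fc.w > 0]))

    def test_triangle_topology_cannot_change(self):
        w = (1.0 - np.eye(3)) * 0.5
        null = rewire_null(FCMatrix(w=w), n_swaps_per_edge=50, seed=0)
        np.testing.assert_array_equal(null.w, w)

    def test_deterministic_under_seed(self, rng):
        fc = random_fc(rng, n=12)
        a = rewire_null(fc, seed=42).w
        b = rewire_null(fc, seed=42).w
        np.testing.assert_array_equal(a, b)

    def test_single_edge_warns_and_copies(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.3
        with pytest.warns(UserWarning, match="fewer than 2"):
            null = rewire_null(FCMatrix(w=w), seed=0)
        np.testing.assert_array_equal(null.w, w)


class TestSmallWorldness:
    def test_self_normalisation_is_unity(self, rng):
        fc = random_fc(rng, n=12, density=0.5)
        gamma, lam, sigma = small_worldness(fc, n_null=1, n_swaps_per_edge=0,
                                            seed=0, mode="weighted")
        assert gamma == pytest.approx(1.0) and lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_random_graph_sigma_near_one(self):
        # an ER graph is statistically its own rewired null
        sigmas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = (rng.random((60, 60)) < 0.2).astype(float)
            w = np.triu(w, 1)
            w = w + w.T
            _, _, sigma = small_worldness(w, n_null=8, seed=seed, mode="binary")
            sigmas.append(sigma)
        assert 0.8 < np.mean(sigmas) < 1.2

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        import networkx as nx

        hits = 0
        for seed in range(20):
            g = nx.watts_strogatz_graph(60, 6, 0.05, seed=seed)
            w = nx.to_numpy_array(g)
            _, _, sigma = small_worldness(w, n_null=8, seed=seed, mode="binary")
            hits += sigma > 1
        assert hits >= 19
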