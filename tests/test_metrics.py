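"""Weighted graph metrics against independent oracles and hand computations."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import structconn as sc

from conftest import random_symmetric_weights


def chain_abc() -> np.ndarray:
    """A-B and B-C with weight 2 each (edge lengths 0.5)."""
    w = np.zeros((3, 3), dtype=int)
    w[0, 1] = w[1, 0] = 2
    w[1, 2] = w[2, 1] = 2
    return w


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths over lengths 1/w."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        if w[i, j] > 0:
            d[i, j] = d[j, i] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


class TestEdgeLengthsAndDistances:
    def test_reciprocal_lengths(self):
        w = chain_abc()
        lengths = sc.edge_lengths(w)
        assert lengths[0, 1] == 0.5
        assert np.isinf(lengths[0, 2])
        assert lengths[0, 0] == 0

    def test_chain_distance_composes(self):
        d = sc.shortest_paths(chain_abc())
        assert d[0, 2] == pytest.approx(1.0)

    def test_isolated_pair_infinite(self):
        d = sc.shortest_paths(np.zeros((2, 2)))
        assert np.isinf(d[0, 1])

    @given(st.integers(2, 8), st.floats(0.1, 0.9), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_floyd_warshall_oracle(self, n, p_edge, seed):
        w = random_symmetric_weights(np.random.default_rng(seed), n, p_edge=p_edge)
        np.testing.assert_allclose(
            sc.shortest_paths(w), floyd_warshall_oracle(w), rtol=1e-12
        )


class TestDensity:
    def test_complete_and_empty(self):
        full = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert sc.network_density(full) == 1.0
        assert sc.network_density(np.zeros((5, 5))) == 0.0

    def test_edge_count_ratio(self, rng):
        w = random_symmetric_weights(rng, 90, p_edge=0.2)
        n_edges = np.count_nonzero(np.triu(w, 1))
        assert sc.network_density(w) == pytest.approx(n_edges / 4005)


class TestEfficiency:
    def test_binary_complete_triangle(self):
        w = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        assert sc.global_efficiency(w) == pytest.approx(1.0)
        assert sc.local_efficiency(w) == pytest.approx(1.0)

    def test_chain_hand_computation(self):
        w = chain_abc()
        ne = sc.nodal_efficiency(w)
        np.testing.assert_allclose(ne, [1.5, 2.0, 1.5])
        assert sc.global_efficiency(w) == pytest.approx(5 / 3)

    def test_empty_graph_zero(self):
        w = np.zeros((4, 4))
        assert sc.global_efficiency(w) == 0.0
        assert not sc.nodal_efficiency(w).any()
        assert sc.local_efficiency(w) == 0.0

    def test_star_graph_local_efficiency_zero(self):
        w = np.zeros((5, 5), dtype=int)
        w[0, 1:] = w[1:, 0] = 1
        assert sc.local_efficiency(w) == 0.0

    @given(st.integers(2, 12), st.floats(0.1, 0.9), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_mean_nodal_efficiency_equals_global(self, n, p_edge, seed):
        w = random_symmetric_weights(np.random.default_rng(seed), n, p_edge=p_edge)
        g, nod = sc.compute_all_metrics(w)
        assert abs(nod.ne.mean() - g.eg) < 1e-12

    def test_adding_edge_monotone(self, rng):
        w = random_symmetric_weights(rng, 10, p_edge=0.3)
        free = np.argwhere(np.triu(w == 0, k=1))
        i, j = free[rng.integers(len(free))]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = 5
        d1, d2 = sc.shortest_paths(w), sc.shortest_paths(w2)
        finite = np.isfinite(d1)
        assert (d2[finite] <= d1[finite] + 1e-12).all()
        assert sc.global_efficiency(w2, d2) >= sc.global_efficiency(w, d1)


class TestPathLength:
    def test_chain_lp(self):
        lp, connected = sc.characteristic_path_length(chain_abc())
        assert lp == pytest.approx(2 / 3)
        assert connected

    def test_binary_complete_lp_one(self):
        w = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
        lp, _ = sc.characteristic_path_length(w)
        assert lp == pytest.approx(1.0)

    def test_isolated_node_excluded_with_flag(self):
        w = np.zeros((4, 4), dtype=int)
        w[0, 1] = w[1, 0] = 1  # node 2,3 isolated from pair
        w[2, 3] = w[3, 2] = 2
        lp, connected = sc.characteristic_path_length(w)
        assert not connected
        assert lp == pytest.approx((1.0 + 0.5) / 2)
        nlp = sc.nodal_path_length(w)
        assert nlp[0] == 1.0 and nlp[2] == 0.5

    def test_fully_disconnected_lp_nan_not_zero(self):
        lp, connected = sc.characteristic_path_length(np.zeros((3, 3)))
        assert np.isnan(lp) and not connected
        assert np.isnan(sc.nodal_path_length(np.zeros((3, 3)))).all()

    def test_harmonic_variant_on_chain(self):
        lp, _ = sc.characteristic_path_length(chain_abc(), mode="harmonic")
        assert lp == pytest.approx(3 / (2 + 2 + 1))


class TestClustering:
    def test_binary_triangle_full_clustering(self):
        w = np.ones((3, 3), dtype=int) - np.eye(3, dtype=int)
        cp, ncp = sc.clustering_coefficients(w)
        np.testing.assert_allclose(ncp, 1.0)
        assert cp == pytest.approx(1.0)

    def test_star_graph_no_triangles(self):
        w = np.zeros((5, 5), dtype=int)
        w[0, 1:] = w[1:, 0] = 1
        cp, ncp = sc.clustering_coefficients(w)
        assert cp == 0.0 and not ncp.any()

    def test_weighted_triangle_brute_force(self):
        # one triangle (0,1,2) with weights 2,2,4 plus pendant node 3
        w = np.zeros((4, 4), dtype=int)
        w[0, 1] = w[1, 0] = 2
        w[0, 2] = w[2, 0] = 2
        w[1, 2] = w[2, 1] = 4
        w[2, 3] = w[3, 2] = 1
        _, ncp = sc.clustering_coefficients(w)
        ww = w / 4.0
        # node 0: neighbors {1,2}; ordered pairs (1,2),(2,1)
        expected0 = 2 * (ww[0, 1] * ww[0, 2] * ww[1, 2]) ** (1 / 3) / (2 * 1)
        assert ncp[0] == pytest.approx(expected0)
        # node 2 has 3 neighbors but only one triangle
        expected2 = 2 * (ww[2, 0] * ww[2, 1] * ww[0, 1]) ** (1 / 3) / (3 * 2)
        assert ncp[2] == pytest.approx(expected2)

    @given(st.integers(3, 10), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_networkx_onnela(self, n, seed):
        w = random_symmetric_weights(np.random.default_rng(seed), n, p_edge=0.5)
        _, ncp = sc.clustering_coefficients(w)
        g = nx.from_numpy_array(w.astype(float))
        expected = nx.clustering(g, weight="weight")
        np.testing.assert_allclose(ncp, [expected[i] for i in range(n)], atol=1e-12)


class TestDegree:
    def test_complete_graph_degree(self):
        w = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        assert (sc.nodal_degree(w) == 4).all()

    def test_binary_vs_weighted(self):
        w = np.zeros((3, 3), dtype=int)
        w[0, 1] = w[1, 0] = 4
        w[0, 2] = w[2, 0] = 6
        assert sc.nodal_degree(w, "binary")[0] == 2
        assert sc.nodal_degree(w, "weighted")[0] == 10
        assert sc.nodal_degree(w)[1] == 1


class TestComputeAllMetrics:
    def test_chain_assembled(self):
        g, nod = sc.compute_all_metrics(chain_abc())
        assert g.density == pytest.approx(2 / 3)
        assert g.eg == pytest.approx(5 / 3)
        assert g.lp == pytest.approx(2 / 3)
        assert g.cp == 0.0
        assert g.eloc == 0.0
        assert g.gamma is None and g.sigma is None

    def test_permutation_invariance_of_global_metrics(self, rng):
        w = random_symmetric_weights(rng, 12, p_edge=0.4)
        perm = rng.permutation(12)
        wp = w[np.ix_(perm, perm)]
        g1, n1 = sc.compute_all_metrics(w)
        g2, n2 = sc.compute_all_metrics(wp)
        for attr in ("density", "cp", "lp", "eg", "eloc"):
            assert getattr(g1, attr) == pytest.approx(getattr(g2, attr))
        np.testing.assert_allclose(n1.ne[perm], n2.ne, atol=1e-12)
        np.testing.assert_allclose(n1.nd[perm], n2.nd)

    def test_dense_binary_limit(self, rng):
        # Erdos-Renyi p -> 1: all metrics approach the complete-graph values
        w = (np.ones((30, 30), dtype=int) - np.eye(30, dtype=int))
        mask = np.triu(rng.random((30, 30)) < 0.02, k=1)
        w[mask | mask.T] = 0
        g, _ = sc.compute_all_metrics(w)
        assert g.density > 0.95
        assert g.cp > 0.95
        assert 1.0 <= g.lp < 1.1
        assert g.eg > 0.95

    def test_empty_graph_all_zero_lp_undefined(self):
        g, nod = sc.compute_all_metrics(np.zeros((90, 90)))
        assert g.density == 0 and g.eg == 0 and g.cp == 0 and g.eloc == 0
        assert np.isnan(g.lp) and not g.connected
        assert np.isnan(nod.nlp).all()
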