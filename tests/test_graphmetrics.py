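import networkx as nx
import numpy as np
import pytest

from fcdiscrim.graphmetrics import (
    NullEnsembleSummary,
    clustering_and_path,
    compute_nodal_metrics,
    degree_preserving_null,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    path_lengths,
    small_world_metrics,
    smallworld_normalize,
)
from fcdiscrim.netbuild import FCNetwork

from oracles import (
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    brute_shortest_path,
    random_weighted_graph,
)


def _path3(w12=1.0, w23=1.0):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w12
    w[1, 2] = w[2, 1] = w23
    return w


def _complete(n, weight=1.0):
    return weight * (np.ones((n, n)) - np.eye(n))


def _star4():
    w = np.zeros((4, 4))
    w[0, 1:] = w[1:, 0] = 1.0
    return w


class TestPathLengths:
    def test_two_hops_on_path_graph(self):
        d = path_lengths(_path3()).d
        assert d[0, 2] == pytest.approx(2.0)

    def test_reciprocal_weight_convention(self):
        d = path_lengths(_path3(w12=2.0)).d
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 1] == pytest.approx(brute_shortest_path(_path3(w12=2.0), 0, 1))

    def test_disconnected_pair_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        d = path_lengths(w).d
        assert np.isinf(d[0, 2])

    def test_triangle_inequality(self):
        w = random_weighted_graph(np.random.default_rng(0), 7, 0.5)
        d = path_lengths(w).d
        for i in range(7):
            for j in range(7):
                for k in range(7):
                    if np.isfinite(d[i, j]) and np.isfinite(d[j, k]):
                        assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestClosedForms:
    def test_complete_graph_efficiency_one(self):
        assert global_efficiency(_complete(5)) == pytest.approx(1.0)

    def test_three_node_path(self):
        w = _path3()
        assert global_efficiency(w) == pytest.approx(5.0 / 6.0)
        e_local, _ = local_efficiency(w)
        np.testing.assert_allclose(e_local, 0.0)
        cp, lp, _, _ = clustering_and_path(w)
        assert cp == pytest.approx(0.0)
        assert lp == pytest.approx(4.0 / 3.0)

    def test_edgeless_graph_zero(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_star_nodal_efficiencies(self):
        w = _star4()
        assert nodal_efficiency(w, 0) == pytest.approx(1.0)
        assert nodal_efficiency(w, 1) == pytest.approx(2.0 / 3.0)

    def test_isolated_node_zero_nodal(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        assert nodal_efficiency(w, 3) == 0.0

    def test_triangle_local_efficiency_one(self):
        e_local, mean = local_efficiency(_complete(3))
        np.testing.assert_allclose(e_local, 1.0)
        assert mean == pytest.approx(1.0)

    def test_k4_local_efficiency_one(self):
        e_local, _ = local_efficiency(_complete(4))
        np.testing.assert_allclose(e_local, 1.0)

    def test_triangle_clustering_and_path(self):
        cp, lp, c_node, _ = clustering_and_path(_complete(3))
        assert cp == pytest.approx(1.0)
        assert lp == pytest.approx(1.0)

    def test_star_clustering_zero(self):
        cp, _, c_node, _ = clustering_and_path(_star4())
        assert cp == 0.0
        np.testing.assert_array_equal(c_node, 0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_random_graphs_match_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 9))
        w = random_weighted_graph(rng, n, float(rng.uniform(0.2, 0.8)))
        assert global_efficiency(w) == pytest.approx(
            brute_global_efficiency(w), abs=1e-10
        )
        np.testing.assert_allclose(
            nodal_efficiency(w), brute_nodal_efficiency(w), atol=1e-10
        )
        e_local, _ = local_efficiency(w)
        np.testing.assert_allclose(e_local, brute_local_efficiency(w), atol=1e-10)

    def test_mean_nodal_equals_global(self):
        for trial in range(20):
            rng = np.random.default_rng(2000 + trial)
            w = random_weighted_graph(rng, 12, 0.3)
            assert np.mean(nodal_efficiency(w)) == pytest.approx(
                global_efficiency(w), abs=1e-12
            )


class TestMonotonicityAndBounds:
    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            w = random_weighted_graph(rng, 10, 0.2)
            zeros = np.argwhere((w == 0) & ~np.eye(10, dtype=bool))
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 2.0)
            assert global_efficiency(w2) >= global_efficiency(w) - 1e-12

    def test_unit_weight_bounds(self):
        rng = np.random.default_rng(4)
        w = (random_weighted_graph(rng, 12, 0.4) > 0).astype(float)
        e = global_efficiency(w)
        e_local, e_loc = local_efficiency(w)
        cp, _, _, _ = clustering_and_path(w)
        assert 0 <= e <= 1
        assert 0 <= e_loc <= 1
        assert 0 <= cp <= 1

    def test_efficiency_bounded_by_max_weight(self):
        rng = np.random.default_rng(5)
        w = random_weighted_graph(rng, 10, 0.5)
        assert global_efficiency(w) <= w.max() + 1e-12


class TestNullEnsemble:
    def test_degree_sequence_and_weights_preserved(self):
        rng = np.random.default_rng(6)
        w = random_weighted_graph(rng, 20, 0.25)
        degrees = (w > 0).sum(1)
        weights = np.sort(w[np.triu_indices(20, 1)][w[np.triu_indices(20, 1)] > 0])
        # re-implement one null draw via the public API and inspect it by
        # checking that the summary is produced from networks with matching
        # invariants: a single null with matched seed must reproduce them
        import networkx as nx

        g = nx.from_numpy_array((w > 0).astype(int))
        m = g.number_of_edges()
        for seed in range(5):
            gk = g.copy()
            nx.double_edge_swap(gk, nswap=10 * m, max_tries=1000 * m, seed=seed)
            assert sorted(d for _, d in gk.degree()) == sorted(degrees)
        summary = degree_preserving_null(w, n_nulls=3, seed=0)
        assert summary.n_nulls == 3

    def test_deterministic_under_seed(self):
        w = random_weighted_graph(np.random.default_rng(7), 15, 0.3)
        a = degree_preserving_null(w, n_nulls=4, seed=5)
        b = degree_preserving_null(w, n_nulls=4, seed=5)
        assert a == b

    def test_too_few_edges_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValueError):
            degree_preserving_null(w, n_nulls=2, seed=0)

    def test_er_graph_is_its_own_null(self):
        w = nx.to_numpy_array(nx.erdos_renyi_graph(60, 0.2, seed=3))
        nulls = degree_preserving_null(w, n_nulls=20, seed=4)
        e = global_efficiency(w)
        assert abs(nulls.mean_e_glob - e) / e < 0.05


class TestSmallWorld:
    def test_self_normalization_is_unity(self):
        w = random_weighted_graph(np.random.default_rng(8), 10, 0.4)
        e = global_efficiency(w)
        _, e_loc = local_efficiency(w)
        cp, lp, _, _ = clustering_and_path(w)
        nulls = NullEnsembleSummary(1, e, e_loc, cp, lp, seed=0)
        gm = smallworld_normalize(e, e_loc, cp, lp, nulls)
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lambda_ == pytest.approx(1.0)
        assert gm.sigma == pytest.approx(1.0)

    def test_zero_null_means_rejected(self):
        nulls = NullEnsembleSummary(1, 0.0, 0.0, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            smallworld_normalize(1.0, 1.0, 1.0, 1.0, nulls)

    def test_sigma_consistency(self):
        w = nx.to_numpy_array(nx.watts_strogatz_graph(60, 6, 0.1, seed=2))
        gm = small_world_metrics(w, n_nulls=5, seed=3)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_)


class TestNodalMetricsContainer:
    def test_all_vectors_aligned_and_nonnegative(self):
        w = random_weighted_graph(np.random.default_rng(9), 15, 0.3)
        nm = compute_nodal_metrics(FCNetwork(w))
        for v in (nm.e_nodal, nm.e_local, nm.c_node, nm.l_node):
            assert v.shape == (15,)
            assert np.all(v >= 0)
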