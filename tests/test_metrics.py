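import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from costnet.errors import ComputationError, ValidationError
from costnet import metrics as M
from costnet.metrics import (NullEnsemble, betweenness,
                             characteristic_path_length,
                             clustering_coefficient, global_efficiency,
                             local_efficiency, nodal_degree, nodal_efficiency,
                             random_null_ensemble, shortest_distances,
                             small_worldness)
from conftest import complete_graph, path_graph, star_graph
from oracles import (oracle_betweenness, oracle_distances,
                     oracle_global_efficiency, oracle_local_efficiency,
                     oracle_nodal_efficiency, random_weighted_graph)


class TestClosedForms:
    def test_path_distances_are_additive(self):
        w = path_graph([1.0, 1.0])
        d = shortest_distances(w)
        assert d[0, 2] == pytest.approx(2.0)
        d_half = shortest_distances(path_graph([0.5, 0.5]))
        assert d_half[0, 2] == pytest.approx(4.0)  # length = 1/weight

    def test_global_efficiency_reference_graphs(self):
        assert global_efficiency(complete_graph(5)) == pytest.approx(1.0)
        assert global_efficiency(np.zeros((4, 4))) == 0.0
        # 3-node path: ordered-pair distances {1, 1, 2} each way
        assert global_efficiency(path_graph([1.0, 1.0])) == pytest.approx(5 / 6)

    def test_nodal_efficiency_star(self):
        w = star_graph(4)
        eff = nodal_efficiency(w)
        assert eff[0] == pytest.approx(1.0)
        assert eff[1] == pytest.approx(0.625)  # (1 + 3 * 0.5) / 4
        iso = np.zeros((3, 3))
        iso[0, 1] = iso[1, 0] = 1.0
        assert nodal_efficiency(iso)[2] == 0.0

    def test_local_efficiency_reference_graphs(self):
        scalar, vec = local_efficiency(complete_graph(3))
        assert scalar == pytest.approx(1.0)
        scalar_star, vec_star = local_efficiency(star_graph(4))
        assert scalar_star == 0.0
        assert np.all(vec_star == 0.0)

    def test_degree_and_handshake(self, rng):
        w = star_graph(4)
        deg = nodal_degree(w)
        assert deg[0] == 4 and np.all(deg[1:] == 1)
        g = random_weighted_graph(10, 0.4, rng)
        assert nodal_degree(g).sum() == 2 * np.count_nonzero(np.triu(g, 1))

    def test_betweenness_star_and_complete(self):
        b = betweenness(star_graph(4))
        assert b[0] == pytest.approx(1.0)
        assert np.all(b[1:] == 0.0)
        assert np.all(betweenness(complete_graph(6)) == 0.0)

    def test_clustering_triangle_and_star(self):
        cp, _ = clustering_coefficient(complete_graph(3))
        assert cp == pytest.approx(1.0)
        assert characteristic_path_length(complete_graph(3)) == pytest.approx(1.0)
        cp_star, _ = clustering_coefficient(star_graph(4))
        assert cp_star == 0.0

    def test_ring_path_length_by_enumeration(self):
        # 6-node ring, unit weights: distances from any node are 1,2,3,2,1
        n = 6
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
        expected = np.mean([1, 2, 3, 2, 1])
        assert characteristic_path_length(w) == pytest.approx(expected)

    def test_empty_graph_conventions(self):
        w = np.zeros((5, 5))
        assert global_efficiency(w) == 0.0
        assert np.all(nodal_efficiency(w) == 0.0)
        assert local_efficiency(w)[0] == 0.0
        assert np.all(nodal_degree(w) == 0)
        assert np.all(betweenness(w) == 0.0)
        assert math.isnan(characteristic_path_length(w))


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,density,seed", [
        (4, 0.5, 0), (5, 0.4, 1), (6, 0.5, 2), (7, 0.35, 3), (7, 0.6, 4),
        (8, 0.4, 5),
    ])
    def test_distances_and_efficiencies_match_enumeration(self, n, density, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(n, density, rng)
        np.testing.assert_allclose(shortest_distances(w), oracle_distances(w),
                                   rtol=1e-10, atol=1e-12)
        assert global_efficiency(w) == pytest.approx(
            oracle_global_efficiency(w), rel=1e-10)
        np.testing.assert_allclose(nodal_efficiency(w),
                                   oracle_nodal_efficiency(w), rtol=1e-10)
        np.testing.assert_allclose(local_efficiency(w)[1],
                                   oracle_local_efficiency(w), rtol=1e-10)
        np.testing.assert_allclose(betweenness(w), oracle_betweenness(w),
                                   rtol=1e-9, atol=1e-12)

    def test_local_efficiency_kernel_matches_numpy_path(self, rng):
        for _ in range(5):
            w = random_weighted_graph(25, 0.3, rng)
            fast = local_efficiency(w)[1]
            reference = M._local_efficiency_numpy(w)[1]
            np.testing.assert_allclose(fast, reference, rtol=1e-12)


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_mean_nodal_equals_global_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng.integers(3, 15), rng.uniform(0.1, 0.8), rng)
        assert nodal_efficiency(w).mean() == pytest.approx(
            global_efficiency(w), rel=1e-12, abs=1e-15)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(10, 0.4, rng)
        perm = rng.permutation(10)
        wp = w[np.ix_(perm, perm)]
        np.testing.assert_allclose(nodal_efficiency(wp),
                                   nodal_efficiency(w)[perm], rtol=1e-10)
        np.testing.assert_allclose(betweenness(wp), betweenness(w)[perm],
                                   rtol=1e-9, atol=1e-12)
        assert global_efficiency(wp) == pytest.approx(global_efficiency(w))
        assert local_efficiency(wp)[0] == pytest.approx(local_efficiency(w)[0])


class TestNullModels:
    def test_degree_sequence_preserved_and_deterministic(self, rng):
        w = random_weighted_graph(20, 0.3, rng)
        first = random_null_ensemble(w, n_null=5, seed=11)
        again = random_null_ensemble(w, n_null=5, seed=11)
        assert first == again
        other = random_null_ensemble(w, n_null=5, seed=12)
        assert other != first

    def test_rewired_degrees_match_input(self, rng):
        from costnet.metrics import _double_edge_swap, _edge_list

        w = random_weighted_graph(15, 0.3, rng)
        edges = _edge_list(w)
        rewired = _double_edge_swap(edges, 15, np.random.default_rng(0),
                                    n_success=10 * len(edges),
                                    max_tries=10 ** 6)
        def degrees(e):
            d = np.zeros(15, dtype=int)
            for a, b in e:
                d[a] += 1
                d[b] += 1
            return d
        np.testing.assert_array_equal(degrees(rewired), degrees(edges))
        # rewiring really changed the topology
        assert set(map(tuple, rewired.tolist())) != set(map(tuple, edges.tolist()))

    def test_er_graph_is_its_own_null(self, rng):
        # an Erdos-Renyi graph should match its degree-preserving nulls in Cp
        w = random_weighted_graph(40, 0.2, rng)
        nulls = random_null_ensemble(w, n_null=30, seed=5)
        cp, _ = clustering_coefficient(w)
        se = nulls.cp_sd * np.sqrt(1 + 1 / nulls.n_null)
        assert abs(cp - nulls.cp_rand) < 3 * se

    def test_too_sparse_to_swap(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ValidationError):
            random_null_ensemble(w, n_null=2, seed=0)
        w[0, 2] = w[2, 0] = 1.0  # two edges sharing node 0: no valid swap
        with pytest.raises(ComputationError):
            random_null_ensemble(w, n_null=2, seed=0)


class TestSmallWorldness:
    def test_self_ratio_is_one(self):
        w = complete_graph(5)
        cp, lp = M.clustering_and_pathlength(w)
        nulls = NullEnsemble(n_null=1, cp_rand=cp, lp_rand=lp, cp_sd=0.0,
                             lp_sd=0.0, seed=0)
        gamma, lam, sigma = small_worldness(w, nulls)
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_degenerate_null_reports_which_denominator(self):
        w = complete_graph(4)
        bad = NullEnsemble(n_null=1, cp_rand=0.0, lp_rand=1.0, cp_sd=0, lp_sd=0,
                           seed=0)
        with pytest.raises(ComputationError, match="Cp_rand"):
            small_worldness(w, bad)
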