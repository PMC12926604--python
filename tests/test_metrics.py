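"""Graph-metric unit tests: closed forms, hand-enumerated oracles, and
structural invariants on small graphs."""

import numpy as np
import pytest

from fcgraph import metrics as M
from conftest import make_net, random_binary_adj, random_weighted_adj
import oracles


class TestShortestPaths:
    def test_path_graph_distance(self, path3):
        d = M.shortest_paths(path3).d
        assert d[0, 2] == 2
        assert d[0, 1] == 1

    def test_disconnected_pairs_infinite(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        d = M.shortest_paths(make_net(a)).d
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_weighted_matches_floyd_warshall(self, rng):
        for _ in range(10):
            w = random_weighted_adj(rng, 10, 0.4)
            d = M.shortest_paths(make_net(w, scheme="weighted")).d
            ref = oracles.distances_fw(w)
            assert np.allclose(d, ref, atol=1e-12)

    def test_symmetry_zero_diagonal_triangle_inequality(self, rng):
        w = random_weighted_adj(rng, 8, 0.5)
        d = M.shortest_paths(make_net(w, scheme="weighted")).d
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        finite = np.isfinite(d)
        for k in range(8):
            lhs = d[:, :]
            rhs = d[:, k, None] + d[None, k, :]
            ok = ~finite | (lhs <= rhs + 1e-9)
            assert ok.all()


class TestEfficiency:
    def test_complete_graph_nodal_efficiency_one(self, k4):
        assert np.allclose(M.nodal_efficiency(k4), 1.0)

    def test_star_hand_enumeration(self, star4):
        # hub reaches all leaves in 1 hop; each leaf: 1 + 1/2 + 1/2 over 3
        e = M.nodal_efficiency(star4)
        assert e[0] == pytest.approx(1.0)
        assert np.allclose(e[1:], 2.0 / 3.0)

    def test_isolated_node_zero(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        e = M.nodal_efficiency(make_net(a))
        assert e[2] == 0.0

    def test_path_global_efficiency(self, path3):
        assert M.global_efficiency(path3) == pytest.approx(5.0 / 6.0)

    def test_empty_graph_zero(self):
        assert M.global_efficiency(make_net(np.zeros((4, 4)))) == 0.0

    def test_local_efficiency_triangle_and_star(self, star4):
        tri = make_net(np.ones((3, 3)) - np.eye(3))
        assert np.allclose(M.local_efficiency(tri), 1.0)
        assert np.allclose(M.local_efficiency(star4), 0.0)

    def test_local_efficiency_matches_subgraph_oracle(self, rng):
        for _ in range(5):
            a = random_binary_adj(rng, 10, 0.45)
            w = random_weighted_adj(rng, 10, 0.45)
            assert np.allclose(
                M.local_efficiency(make_net(a)),
                oracles.local_efficiency_oracle(a),
                atol=1e-9,
            )
            assert np.allclose(
                M.local_efficiency(make_net(w, scheme="weighted")),
                oracles.local_efficiency_oracle(w),
                atol=1e-9,
            )


class TestClusteringDegreeDensity:
    def test_k4_closed_forms(self, k4):
        assert np.allclose(M.clustering_coefficient(k4), 1.0)
        assert M.transitivity(k4) == pytest.approx(1.0)
        assert np.allclose(M.degree(k4), 3.0)
        assert M.density(k4) == pytest.approx(1.0)

    def test_k4_minus_edge_triangle_enumeration(self):
        a = np.ones((4, 4)) - np.eye(4)
        a[2, 3] = a[3, 2] = 0  # remove edge c-d
        c = M.clustering_coefficient(make_net(a))
        assert c[0] == pytest.approx(2.0 / 3.0)
        assert c[1] == pytest.approx(2.0 / 3.0)
        assert c[2] == pytest.approx(1.0)
        assert c[3] == pytest.approx(1.0)

    def test_star_zero_clustering(self, star4):
        assert np.allclose(M.clustering_coefficient(star4), 0.0)
        assert M.transitivity(star4) == 0.0

    def test_path_density(self, path3):
        assert M.density(path3) == pytest.approx(2.0 / 3.0)

    def test_weighted_strength(self):
        w = np.full((3, 3), 0.5) - np.diag([0.5] * 3)
        net = make_net(w, scheme="weighted")
        assert np.allclose(M.degree(net), 1.0)


class TestBetweenness:
    def test_star_hub(self, star4):
        b = M.betweenness(star4)
        assert b[0] == pytest.approx(3.0)  # (n-1)(n-2)/2 leaf pairs
        assert np.allclose(b[1:], 0.0)

    def test_complete_graph_zero(self, k4):
        assert np.allclose(M.betweenness(k4), 0.0)

    def test_matches_reference_on_random_graphs(self, rng):
        for _ in range(8):
            a = random_binary_adj(rng, 9, 0.4)
            assert np.allclose(
                M.betweenness(make_net(a)), oracles.betweenness_oracle(a), atol=1e-9
            )
            w = random_weighted_adj(rng, 9, 0.4)
            assert np.allclose(
                M.betweenness(make_net(w, scheme="weighted")),
                oracles.betweenness_oracle(w),
                atol=1e-7,
            )


class TestEigenvectorCentrality:
    def test_complete_graph_uniform(self, k4):
        assert np.allclose(M.eigenvector_centrality(k4), 0.5)

    def test_star_hub_ratio(self, star4):
        # 2x2 reduced eigensystem: hub value = sqrt(3) x leaf value
        v = M.eigenvector_centrality(star4)
        assert v[0] / v[1] == pytest.approx(np.sqrt(3), rel=1e-8)

    def test_defining_property(self, rng):
        a = random_weighted_adj(rng, 10, 0.5)
        net = make_net(a, scheme="weighted")
        v = M.eigenvector_centrality(net)
        lam = v @ a @ v
        assert np.allclose(a @ v, lam * v, atol=1e-8)

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError, match="edgeless"):
            M.eigenvector_centrality(make_net(np.zeros((3, 3))))


class TestAssortativity:
    def test_path4_hand_value(self):
        a = np.zeros((4, 4))
        for i in range(3):
            a[i, i + 1] = a[i + 1, i] = 1
        assert M.assortativity(make_net(a)) == pytest.approx(-0.5)

    def test_regular_graph_undefined(self):
        cycle = np.zeros((5, 5))
        for i in range(5):
            cycle[i, (i + 1) % 5] = cycle[(i + 1) % 5, i] = 1
        assert np.isnan(M.assortativity(make_net(cycle)))

    def test_matches_edge_list_oracle(self, rng):
        for _ in range(8):
            a = random_binary_adj(rng, 10, 0.4)
            ref = oracles.assortativity_oracle(a)
            mine = M.assortativity(make_net(a))
            if np.isnan(ref):
                assert np.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-12)


class TestCommunities:
    def test_two_triangles_exact(self, two_triangles):
        part, q = M.detect_communities(two_triangles, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(part[:3])) == 1 and len(set(part[3:])) == 1
        assert part[0] != part[3]

    def test_complete_graph_trivial_partition(self, k4):
        part, q = M.detect_communities(k4, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(set(part)) == 1

    def test_planted_two_block_recovery(self, rng):
        n = 16
        blocks = np.repeat([0, 1], n // 2)
        a = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.9 if blocks[i] == blocks[j] else 0.05
                if rng.random() < p:
                    a[i, j] = a[j, i] = 1
        part, _ = M.detect_communities(make_net(a), seed=0)
        # same planted block -> same community, across blocks -> different
        assert len(set(part[: n // 2])) == 1
        assert len(set(part[n // 2 :])) == 1
        assert part[0] != part[-1]

    def test_participation_within_module_zero(self, two_triangles):
        part, _ = M.detect_communities(two_triangles, seed=0)
        assert np.allclose(M.participation_coefficient(two_triangles, part), 0.0)

    def test_participation_even_split(self):
        # node 0 has one edge into each of two modules
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[0, 2] = a[2, 0] = 1
        p = M.participation_coefficient(make_net(a), np.array([0, 1, 2]))
        assert p[0] == pytest.approx(0.5)

    def test_isolated_node_participation_zero(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        p = M.participation_coefficient(make_net(a), np.array([0, 0, 1]))
        assert p[2] == 0.0

    def test_partition_must_cover_nodes(self, k4):
        with pytest.raises(ValueError):
            M.participation_coefficient(k4, np.array([0, 0, 1]))


class TestSmallWorld:
    def test_degenerate_nulls_sigma_exactly_one(self, rng):
        a = random_binary_adj(rng, 12, 0.5)
        res = M.small_world_sigma(make_net(a), n_null=3, rewire_factor=0, seed=0)
        assert res.sigma == 1.0
        assert res.c_observed == res.c_random_mean
        assert res.l_observed == res.l_random_mean

    def test_rewiring_preserves_degree_sequence(self, rng):
        a = random_binary_adj(rng, 14, 0.4)
        net = make_net(a)
        null, n_ok = M.rewire_degree_preserving(net, 200, rng)
        assert n_ok > 0
        assert np.array_equal(
            np.sort(null.adjacency.sum(1)), np.sort(net.adjacency.sum(1))
        )

    def test_rewiring_weighted_preserves_weight_multiset(self, rng):
        w = random_weighted_adj(rng, 14, 0.4)
        net = make_net(w, scheme="weighted")
        null, _ = M.rewire_degree_preserving(net, 200, rng)
        assert np.allclose(
            np.sort(null.adjacency[np.triu_indices(14, 1)]),
            np.sort(net.adjacency[np.triu_indices(14, 1)]),
        )

    def test_seed_reproducible(self, rng):
        a = random_binary_adj(rng, 12, 0.4)
        r1 = M.small_world_sigma(make_net(a), n_null=4, seed=7)
        r2 = M.small_world_sigma(make_net(a), n_null=4, seed=7)
        assert r1.sigma == r2.sigma


class TestComputeAll:
    def test_k4_closed_form_bundle(self, k4):
        g, r = M.compute_all(k4, M.MetricConfig(n_null=2, rewire_factor=0, seed=0))
        assert g.density == pytest.approx(1.0)
        assert g.global_efficiency == pytest.approx(1.0)
        assert g.transitivity == pytest.approx(1.0)
        assert g.small_world_sigma == pytest.approx(1.0)  # degenerate nulls
        assert g.n_components == 1
        assert np.allclose(r.clustering, 1.0)
        assert np.allclose(r.betweenness, 0.0)
        assert np.allclose(r.nodal_efficiency, 1.0)

    def test_fields_match_standalone_operations(self, rng):
        a = random_binary_adj(rng, 10, 0.45)
        net = make_net(a)
        cfg = M.MetricConfig(n_null=2, rewire_factor=0, seed=3)
        g, r = M.compute_all(net, cfg)
        assert g.global_efficiency == pytest.approx(M.global_efficiency(net))
        assert g.density == pytest.approx(M.density(net))
        assert g.transitivity == pytest.approx(M.transitivity(net))
        assert np.allclose(r.degree, M.degree(net))
        assert np.allclose(r.betweenness, M.betweenness(net))
        assert np.allclose(r.local_efficiency, M.local_efficiency(net))
        part, q = M.detect_communities(net, seed=3)
        assert g.modularity_q == pytest.approx(q)

    def test_disconnected_graph_components_and_finite_efficiency(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1
        g, r = M.compute_all(
            make_net(a), M.MetricConfig(n_null=2, rewire_factor=0, seed=0)
        )
        assert g.n_components == 2
        assert np.isfinite(g.global_efficiency)
        assert np.all(np.isfinite(r.nodal_efficiency))

    def test_metric_selection_leaves_others_nan(self, k4):
        g, r = M.compute_all(k4, M.MetricConfig(metrics=("degree", "density")))
        assert np.allclose(r.degree, 3.0)
        assert g.density == pytest.approx(1.0)
        assert np.isnan(g.global_efficiency)
        assert np.all(np.isnan(r.betweenness))


class TestInvariants:
    def test_permutation_equivariance(self, rng):
        a = random_weighted_adj(rng, 9, 0.5)
        net = make_net(a, scheme="weighted")
        perm = rng.permutation(9)
        pa = a[np.ix_(perm, perm)]
        pnet = make_net(pa, scheme="weighted")
        cfg = M.MetricConfig(n_null=1, rewire_factor=0, seed=0, n_restarts=4)
        g1, r1 = M.compute_all(net, cfg)
        g2, r2 = M.compute_all(pnet, cfg)
        assert g1.global_efficiency == pytest.approx(g2.global_efficiency)
        assert g1.transitivity == pytest.approx(g2.transitivity)
        assert np.allclose(r1.degree[perm], r2.degree)
        assert np.allclose(r1.nodal_efficiency[perm], r2.nodal_efficiency)
        assert np.allclose(r1.betweenness[perm], r2.betweenness, atol=1e-9)

    def test_weight_scaling(self, rng):
        w = random_weighted_adj(rng, 8, 0.5)
        net = make_net(w, scheme="weighted")
        scaled = make_net(3.0 * w, scheme="weighted")
        assert np.allclose(M.degree(scaled), 3.0 * M.degree(net))
        # binary view unchanged
        b = (w > 0).astype(float)
        assert M.density(make_net(b)) == M.density(make_net((3 * w > 0).astype(float)))

    def test_adding_edge_monotonicity(self, rng):
        a = random_binary_adj(rng, 8, 0.3)
        net = make_net(a)
        zeros = np.argwhere(np.triu(a == 0, 1))
        i, j = zeros[0]
        a2 = a.copy()
        a2[i, j] = a2[j, i] = 1
        net2 = make_net(a2)
        assert M.density(net2) > M.density(net)
        assert M.degree(net2).sum() > M.degree(net).sum()
        assert M.global_efficiency(net2) >= M.global_efficiency(net)
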