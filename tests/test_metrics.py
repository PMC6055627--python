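"""Graph parameters against worked toy examples and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph_adj
from gmnet import (
    BinaryNetwork,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    connectivity_density,
    degree,
    density_from_counts,
    normalized_metrics,
    rewire_reference,
)
from gmnet.graph import ReferenceEnsemble, path_length_harmonic, shortest_path_matrix
from oracles import betweenness_ordered, clustering_nodal, path_length_stats


def net_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    return BinaryNetwork(adjacency=adj)


def star(n_leaves):
    return net_from_edges(n_leaves + 1, [(0, i) for i in range(1, n_leaves + 1)])


def complete(n):
    return net_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


class TestWorkedExamples:
    """The schematic toy-network values: degree 5, path 3, clustering 1/3,
    star-pattern betweenness, density 23% = 7/30."""

    def test_degree_five_node(self):
        nodal, _ = degree(star(5))
        assert nodal[0] == 5

    def test_path_length_three_on_path_graph(self):
        p4 = net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert shortest_path_matrix(p4)[0, 3] == 3

    def test_clustering_one_third(self):
        # center 0 with neighbors 1,2,3; a single neighbor-neighbor edge
        g = net_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2)])
        nodal, _ = clustering_coefficient(g)
        assert nodal[0] == pytest.approx(1 / 3)

    def test_star_betweenness_center_maximal_leaves_zero(self):
        raw, _, _ = betweenness_centrality(star(5))
        assert np.all(raw[1:] == 0)
        assert raw[0] == pytest.approx(5 * 4)  # all ordered leaf pairs

    def test_density_seven_of_thirty_is_23_percent(self):
        assert density_from_counts(7, 30) == pytest.approx(23.333, abs=1e-3)


class TestBasicMetrics:
    def test_isolated_node_degree_zero(self):
        nodal, mean = degree(net_from_edges(3, [(0, 1)]))
        assert nodal[2] == 0
        assert mean == pytest.approx(2 / 3)

    def test_complete_graph_degree(self):
        nodal, _ = degree(complete(5))
        assert np.all(nodal == 4)

    def test_density_extremes(self):
        assert connectivity_density(complete(6)) == pytest.approx(100.0)
        assert connectivity_density(net_from_edges(6, [])) == 0.0
        with pytest.raises(ValueError):
            connectivity_density(net_from_edges(1, []))

    def test_triangle_clustering_one(self):
        _, mean = clustering_coefficient(complete(3))
        assert mean == 1.0

    def test_star_center_clustering_zero(self):
        nodal, _ = clustering_coefficient(star(4))
        assert nodal[0] == 0.0

    def test_complete_graph_path_length_one(self):
        _, g, _ = characteristic_path_length(complete(6))
        assert g == 1.0

    def test_complete_graph_betweenness_zero(self):
        raw, mean, _ = betweenness_centrality(complete(5))
        assert np.all(raw == 0)

    def test_disconnected_pairs_excluded_with_warning(self):
        two_cliques = net_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        with pytest.warns(UserWarning, match="unreachable"):
            _, g, n_unreach = characteristic_path_length(two_cliques)
        assert g == 1.0
        assert n_unreach == 9

    def test_fully_disconnected_rejected(self):
        with pytest.raises(ValueError):
            characteristic_path_length(net_from_edges(4, []))

    def test_harmonic_variant_penalizes_disconnection(self):
        connected = net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        split = net_from_edges(4, [(0, 1), (2, 3)])
        assert path_length_harmonic(split) > path_length_harmonic(connected)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_metrics_match_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        adj = random_graph_adj(n, float(rng.uniform(0.25, 0.6)), rng)
        net = BinaryNetwork(adjacency=adj)

        nodal_c, mean_c = clustering_coefficient(net)
        assert np.allclose(nodal_c, clustering_nodal(adj), atol=1e-10)

        o_nodal, o_global = path_length_stats(adj)
        if np.isfinite(o_global):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nodal_l, global_l, _ = characteristic_path_length(net)
            assert global_l == pytest.approx(o_global, abs=1e-10)
            assert np.allclose(nodal_l, o_nodal, atol=1e-10, equal_nan=True)

        raw, _, _ = betweenness_centrality(net)
        assert np.allclose(raw, betweenness_ordered(adj), atol=1e-10)

        assert connectivity_density(net) == pytest.approx(
            100.0 * adj.sum() / (n * (n - 1)), abs=1e-10
        )


class TestNullModel:
    def test_references_preserve_degree_sequence(self):
        rng = np.random.default_rng(3)
        net = BinaryNetwork(adjacency=random_graph_adj(30, 0.2, rng))
        ens = rewire_reference(net, n_references=5, seed=1)
        src = sorted(d for _, d in net.to_networkx().degree())
        for ref in ens.graphs:
            assert sorted(d for _, d in ref.degree()) == src

    def test_triangle_admits_no_swap_and_returns_input(self):
        k3 = complete(3)
        with pytest.warns(UserWarning, match="swap"):
            ens = rewire_reference(k3, n_references=3, seed=0)
        for ref in ens.graphs:
            assert sorted(ref.edges()) == sorted(k3.to_networkx().edges())

    def test_ring_lattice_references_lose_clustering(self):
        g = nx.watts_strogatz_graph(40, 6, 0.0, seed=1)  # pure ring lattice
        net = BinaryNetwork(adjacency=nx.to_numpy_array(g).astype(bool))
        ens = rewire_reference(net, n_references=20, seed=2)
        _, c_in = clustering_coefficient(net)
        # direct recomputation on each reference
        ref_cs = [clustering_coefficient(BinaryNetwork(adjacency=nx.to_numpy_array(r).astype(bool)))[1] for r in ens.graphs]
        assert np.allclose(ref_cs, ens.clustering_global)
        assert np.mean(ref_cs) < c_in

    def test_identity_ensemble_gives_unit_normalized_metrics(self):
        rng = np.random.default_rng(5)
        net = BinaryNetwork(adjacency=random_graph_adj(25, 0.3, rng))
        _, c = clustering_coefficient(net)
        _, l, _ = characteristic_path_length(net)
        ens = ReferenceEnsemble(
            graphs=[net.to_networkx()],
            clustering_global=np.array([c]),
            path_length_global=np.array([l]),
            seed=0,
            swaps_per_edge=0,
        )
        gamma, lam, sw = normalized_metrics(net, ens)
        assert (gamma, lam, sw) == (1.0, 1.0, 1.0)

    def test_small_world_ring_with_light_rewiring(self):
        g = nx.watts_strogatz_graph(100, 8, 0.05, seed=3)
        net = BinaryNetwork(adjacency=nx.to_numpy_array(g).astype(bool))
        ens = rewire_reference(net, n_references=10, seed=4)
        gamma, lam, sw = normalized_metrics(net, ens)
        # near-lattice: clustering far above random, path length only mildly
        # elevated, hence a small-world coefficient well above 1
        assert gamma > 1.5
        assert 1.0 <= lam < gamma
        assert sw > 1.0

    def test_sparse_triangle_free_graph_rejects_gamma(self):
        path = net_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        ens = rewire_reference(path, n_references=3, seed=5)
        if float(ens.clustering_global.mean()) == 0.0:
            with pytest.raises(ValueError, match="gamma"):
                normalized_metrics(path, ens)


class TestConsistencyInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_density_equals_degree_over_size_identity(self, seed):
        rng = np.random.default_rng(seed)
        net = BinaryNetwork(adjacency=random_graph_adj(20, 0.3, rng))
        _, mean_deg = degree(net)
        assert connectivity_density(net) == pytest.approx(
            mean_deg / (net.n_nodes - 1) * 100, abs=1e-10
        )

    def test_metrics_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(9)
        adj = random_graph_adj(15, 0.4, rng)
        perm = rng.permutation(15)
        net1 = BinaryNetwork(adjacency=adj)
        net2 = BinaryNetwork(adjacency=adj[np.ix_(perm, perm)])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = compute_metrics(net1, n_references=5, seed=0)
            m2 = compute_metrics(net2, n_references=5, seed=0)
        for key in ("degree", "connectivity_density", "clustering", "path_length", "betweenness"):
            assert m1.to_dict()[key] == pytest.approx(m2.to_dict()[key], abs=1e-10)

    def test_compute_metrics_assembles_consistent_set(self):
        g = nx.watts_strogatz_graph(60, 6, 0.1, seed=7)
        net = BinaryNetwork(adjacency=nx.to_numpy_array(g).astype(bool))
        m = compute_metrics(net, n_references=5, seed=1)
        assert m.small_world == pytest.approx(m.gamma / m.lambda_)
        assert m.connectivity_density == pytest.approx(
            m.degree_global / (m.size - 1) * 100, abs=1e-10
        )
        assert 0 <= m.clustering_global <= 1
        assert len(m.nodal) == m.size
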