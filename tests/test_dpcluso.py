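"""Overlapping density clustering: weights, growth policy, coverage."""

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from mbnet import dpcluso as dp

from conftest import random_graph


def graph_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


class TestEdgeWeights:
    def test_triangle_all_weights_one(self):
        g = nx.complete_graph(3)
        assert set(dp.edge_weights(g).values()) == {1}

    def test_star_all_weights_zero(self):
        g = nx.star_graph(3)
        assert set(dp.edge_weights(g).values()) == {0}

    def test_matches_brute_force_neighbor_intersection(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_graph(rng, n_max=20)
            ew = dp.edge_weights(g)
            for u, v in g.edges:
                expected = len(set(g.neighbors(u)) & set(g.neighbors(v)))
                assert ew[(min(u, v), max(u, v))] == expected


class TestClusterProperty:
    def test_two_edges_into_triangle(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("n", "a"), ("n", "b")])
        assert dp.cluster_property("n", {"a", "b", "c"}, g) == pytest.approx(2 / 3)

    def test_disconnected_node_scores_zero(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_node("n")
        assert dp.cluster_property("n", {"a", "b", "c"}, g) == 0.0

    def test_member_node_is_contract_violation(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValueError):
            dp.cluster_property(0, {0, 1}, g)

    def test_matches_definition_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            g = random_graph(rng, n_max=15)
            nodes = sorted(g.nodes)
            if len(nodes) < 3:
                continue
            k = set(nodes[: int(rng.integers(2, len(nodes)))])
            outside = [n for n in nodes if n not in k]
            if not outside:
                continue
            n = outside[0]
            e_nk = sum(1 for m in k if g.has_edge(n, m))
            sub = g.subgraph(k)
            d_k = (
                2 * sub.number_of_edges() / (len(k) * (len(k) - 1))
                if len(k) > 1 else 1.0
            )
            expected = 0.0 if d_k == 0 else e_nk / (d_k * len(k))
            assert dp.cluster_property(n, k, g) == pytest.approx(expected, abs=1e-12)


class TestGrowAndCluster:
    def test_single_edge_graph(self):
        g = graph_from_edges([("a", "b")])
        run = dp.dpcluso(g, dp.ClusterParams(d_in=1.0))
        assert [set(c.nodes) for c in run.clusters] == [{"a", "b"}]
        assert run.clusters[0].density == 1.0

    def test_k4_grows_fully_at_half_density(self):
        g = nx.complete_graph(4)
        run = dp.dpcluso(g, dp.ClusterParams(d_in=0.5))
        assert set(run.clusters[0].nodes) == set(range(4))

    def test_two_k4s_sharing_a_node_stay_separate_at_high_density(self):
        g = nx.Graph()
        for block in (["v", "a1", "a2", "a3"], ["v", "b1", "b2", "b3"]):
            g.add_edges_from(itertools.combinations(block, 2))
        run = dp.dpcluso(g, dp.ClusterParams(d_in=0.9))
        multi = [set(c.nodes) for c in run.clusters if c.size > 1]
        assert len(multi) == 2
        assert all(len(c) == 4 and "v" in c for c in multi)

    def test_edgeless_graph_gives_singletons(self):
        g = nx.empty_graph(3)
        run = dp.dpcluso(g, dp.ClusterParams(d_in=0.5))
        assert sorted(c.size for c in run.clusters) == [1, 1, 1]
        assert all(c.density == 1.0 for c in run.clusters)

    def test_disjoint_cliques_recovered(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(["a", "b", "c"], 2))
        g.add_edges_from(itertools.combinations(["w", "x", "y", "z"], 2))
        run = dp.dpcluso(g, dp.ClusterParams(d_in=0.5))
        multi = sorted([tuple(sorted(c.nodes)) for c in run.clusters if c.size > 1])
        assert multi == [("a", "b", "c"), ("w", "x", "y", "z")]

    def test_clusters_at_full_density_are_cliques_covering_all_nodes(self):
        # At d_in = 1.0 every multi-node cluster must induce a clique and
        # every node must be covered by one cluster.
        rng = np.random.default_rng(17)
        for _ in range(50):
            g = random_graph(rng, n_max=9, p_max=0.8)
            run = dp.dpcluso(g, dp.ClusterParams(d_in=1.0))
            covered = set()
            for c in run.clusters:
                covered |= c.nodes
                sub = g.subgraph(c.nodes)
                n = c.size
                assert sub.number_of_edges() == n * (n - 1) // 2
            assert covered == set(g.nodes)


class TestInvariants:
    @pytest.mark.parametrize("d_in", [0.1, 0.5, 0.9])
    def test_coverage_density_connectivity(self, d_in):
        rng = np.random.default_rng(int(d_in * 100))
        for _ in range(40):
            g = random_graph(rng)
            run = dp.dpcluso(g, dp.ClusterParams(d_in=d_in))
            covered = set()
            for c in run.clusters:
                covered |= c.nodes
                if c.size >= 2:
                    sub = g.subgraph(c.nodes)
                    density = Fraction(2 * sub.number_of_edges(),
                                       c.size * (c.size - 1))
                    assert density >= Fraction(d_in).limit_denominator(10**6)
                    assert nx.is_connected(sub)
            assert covered == set(g.nodes)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            g = random_graph(rng)
            edges = list(g.edges)
            rng.shuffle(edges)
            g2 = nx.Graph()
            g2.add_nodes_from(g.nodes)
            g2.add_edges_from(edges)
            r1 = dp.dpcluso(g, dp.ClusterParams(d_in=0.3))
            r2 = dp.dpcluso(g2, dp.ClusterParams(d_in=0.3))
            assert [c.nodes for c in r1.clusters] == [c.nodes for c in r2.clusters]


class TestDensitySweep:
    def test_single_density_equals_dpcluso(self):
        g = nx.karate_club_graph()
        (run,) = dp.density_sweep(g, densities=[0.4])
        direct = dp.dpcluso(g, dp.ClusterParams(d_in=0.4))
        assert [c.nodes for c in run.clusters] == [c.nodes for c in direct.clusters]

    def test_summary_matches_recomputation(self):
        g = nx.karate_club_graph()
        runs = dp.density_sweep(g, densities=[0.2, 0.8])
        table = dp.summary_table(runs)
        for row, run in zip(table.itertuples(index=False), runs):
            sizes = [c.size for c in run.clusters]
            assert row[1] == len(sizes)
            assert row[2] == max(sizes)
            assert row[3] == pytest.approx(sum(sizes) / len(sizes))

    def test_average_size_decreases_with_density(self, demo_world):
        # Finer (higher-density) clusterings cannot produce larger
        # average clusters than the coarsest setting on the demo network.
        _, _, net = demo_world
        runs = dp.density_sweep(net, densities=[0.1, 0.9])
        avg = {r.params.d_in: r.summary()["average_size"] for r in runs}
        assert avg[0.9] <= avg[0.1]

    def test_empty_density_list_rejected(self):
        with pytest.raises(ValueError):
            dp.density_sweep(nx.complete_graph(3), densities=[])
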