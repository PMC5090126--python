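import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from corrnet import analyze, density, rank_hubs
from corrnet.topology import (average_shortest_path, betweenness_centrality,
                              clustering_coefficients, diameter,
                              edge_betweenness, fit_power_law, transitivity,
                              vertex_degrees)
from oracles import (average_shortest_path_oracle, betweenness_oracle,
                     clustering_oracle, diameter_oracle,
                     edge_betweenness_oracle, transitivity_oracle)


def path_graph(n):
    g = nx.Graph()
    nx.add_path(g, [f"p{i}" for i in range(n)])
    return g


def star_graph(leaves=4):
    g = nx.Graph()
    g.add_edges_from(("hub", f"leaf{i}") for i in range(leaves))
    return g


class TestGlobalMetrics:
    @pytest.mark.parametrize("v,e,expected", [
        (16, 27, 0.225),   # unique-interaction network, first condition
        (22, 84, 84 / 231),  # unique-interaction network, second condition
        (4, 6, 1.0),       # K4
    ])
    def test_density_identity(self, v, e, expected, rng):
        g = nx.gnm_random_graph(v, e, seed=int(rng.integers(2**31)))
        assert density(g) == pytest.approx(expected, abs=1e-12)

    def test_density_undefined_below_two_vertices(self):
        g = nx.Graph()
        g.add_node("only")
        assert math.isnan(density(g))

    def test_transitivity_triangle_and_path(self):
        assert transitivity(nx.complete_graph(3)) == (1.0, True)
        assert transitivity(path_graph(3)) == (0.0, True)

    def test_transitivity_triangle_with_pendant(self):
        """Triples sum C(deg,2) = 1+1+3 = 5 over one triangle -> 3/5."""
        g = nx.complete_graph(3)
        g.add_edge(0, 3)
        val, defined = transitivity(g)
        assert defined and val == pytest.approx(0.6)

    def test_transitivity_undefined_without_triples(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        assert transitivity(g) == (0.0, False)

    def test_diameter_path_and_complete(self):
        assert diameter(path_graph(5)) == (4, 1)
        assert diameter(nx.complete_graph(6)) == (1, 1)

    def test_diameter_largest_component(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert diameter(g) == (1, 2)

    def test_diameter_requires_an_edge(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        with pytest.raises(ValueError):
            diameter(g)

    def test_average_shortest_path_examples(self):
        assert average_shortest_path(nx.complete_graph(3)) == pytest.approx(1.0)
        # P3 distances: 1, 1, 2 -> 4/3
        assert average_shortest_path(path_graph(3)) == pytest.approx(4 / 3)


class TestPerElementMetrics:
    def test_degrees_sum_to_twice_edges(self, rng):
        for _ in range(20):
            g = random_graph(rng)
            assert sum(vertex_degrees(g).values()) == 2 * g.number_of_edges()

    def test_star_and_path_betweenness(self):
        b = betweenness_centrality(star_graph(4))
        assert b["hub"] == pytest.approx(1.0)
        assert all(b[f"leaf{i}"] == 0 for i in range(4))
        b = betweenness_centrality(path_graph(3))
        assert b["p1"] == pytest.approx(1.0)
        assert b["p0"] == b["p2"] == 0

    def test_complete_graph_betweenness_zero(self):
        assert all(v == 0 for v in betweenness_centrality(
            nx.complete_graph(5)).values())

    def test_edge_betweenness_p3_and_triangle(self):
        eb = edge_betweenness(path_graph(3))
        assert all(v == pytest.approx(2.0) for v in eb.values())
        eb = edge_betweenness(nx.complete_graph(3))
        assert len(set(round(v, 9) for v in eb.values())) == 1

    def test_bridge_carries_all_cross_pairs(self):
        """Bridge between two triangles lies on all 3x3 cross shortest paths."""
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                          ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                          ("a1", "b1")])
        eb = edge_betweenness(g)
        assert eb[frozenset(("a1", "b1"))] == pytest.approx(9.0)

    def test_clustering_examples(self):
        c = clustering_coefficients(nx.complete_graph(3))
        assert all(v == 1.0 for v in c.values())
        c = clustering_coefficients(path_graph(3))
        assert c["p1"] == 0.0  # neighbors not connected
        assert c["p0"] == 0.0  # degree < 2


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self, rng):
        """Spot-check against exhaustive path enumeration on random graphs."""
        for _ in range(30):
            g = random_graph(rng)
            nodes, edges = list(g.nodes), list(g.edges)
            btw = betweenness_centrality(g)
            orc = betweenness_oracle(nodes, edges)
            for n in nodes:
                assert btw[n] == pytest.approx(orc[n], abs=1e-9)
            eb = edge_betweenness(g)
            orc_eb = edge_betweenness_oracle(nodes, edges)
            for e in edges:
                assert eb[frozenset(e)] == pytest.approx(orc_eb[frozenset(e)],
                                                         abs=1e-9)
            clus = clustering_coefficients(g)
            orc_c = clustering_oracle(nodes, edges)
            for n in nodes:
                assert clus[n] == pytest.approx(orc_c[n], abs=1e-9)
            t, defined = transitivity(g)
            orc_t = transitivity_oracle(nodes, edges)
            if orc_t is None:
                assert not defined
            else:
                assert t == pytest.approx(orc_t, abs=1e-9)
            if edges:
                assert diameter(g) == diameter_oracle(nodes, edges)
                assert average_shortest_path(g) == pytest.approx(
                    average_shortest_path_oracle(nodes, edges), abs=1e-9)


class TestPowerLaw:
    def test_guard_on_too_few_distinct_degrees(self):
        exp, r2 = fit_power_law(star_graph(5))  # degrees {1, 5} only
        assert math.isnan(exp) and math.isnan(r2)
        exp, r2 = fit_power_law(nx.complete_graph(4))  # regular
        assert math.isnan(exp)

    def test_preferential_attachment_exponent(self):
        """Mean log-log fit exponent over seeded scale-free graphs lands in
        the heavy-tail band; single draws are noisy, the mean is stable."""
        exps = []
        for seed in range(20):
            g = nx.barabasi_albert_graph(200, 2, seed=seed)
            exp, r2 = fit_power_law(g)
            assert 0 <= r2 <= 1
            exps.append(exp)
        assert 1.5 <= np.mean(exps) <= 3.5


class TestAnalyzeAndHubs:
    def test_k4_report(self):
        rep = analyze(nx.complete_graph(4))
        g = rep.global_metrics
        assert g["density"] == 1.0
        assert g["diameter"] == 1
        assert g["transitivity"] == 1.0
        assert rep.vertex_table["degree"].sum() == 2 * g["edge_count"]

    def test_degree_sum_invariant(self, rng):
        for _ in range(10):
            rep = analyze(random_graph(rng))
            assert rep.vertex_table["degree"].sum() == 2 * rep.edge_count

    def test_empty_graph_report(self):
        rep = analyze(nx.Graph())
        assert rep.vertex_count == 0 and rep.edge_count == 0

    def test_determinism(self, rng):
        g = random_graph(rng, n_max=8)
        r1, r2 = analyze(g), analyze(g)
        assert r1.vertex_table.to_csv() == r2.vertex_table.to_csv()
        assert r1.global_metrics == r2.global_metrics

    def test_hub_ranking_betweenness_then_degree_then_label(self):
        # star + pendant chain: hub has top betweenness; ties fall to degree
        g = nx.Graph()
        g.add_edges_from([("hub", l) for l in "abcd"])
        rep = analyze(g)
        ranked = rank_hubs(rep)
        assert ranked[0] == "hub"
        assert ranked[1:] == sorted(ranked[1:])  # tie -> label order

    def test_hub_ranking_prefers_betweenness_over_degree(self):
        # b bridges two cliques: lower degree than clique members but all
        # cross traffic passes through it
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                          ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                          ("a1", "x"), ("x", "b1")])
        rep = analyze(g)
        assert rank_hubs(rep)[0] == "x"

    def test_singleton_network(self):
        g = nx.Graph()
        g.add_node("only")
        rep = analyze(g)
        assert rank_hubs(rep) == ["only"]
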