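import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trinetomics import (CommunityPartition, TransOmicsGraph, community_summary,
                         edge_betweenness, girvan_newman, modularity, summary_table)


def _graph(edges, domains=None, lengths=None):
    g = TransOmicsGraph()
    nodes = sorted({n for e in edges for n in e})
    for n in nodes:
        g.add_node(n, (domains or {}).get(n, "metabolite"))
    for e in edges:
        g.add_edge(*e, rho=0.0, length=(lengths or {}).get(tuple(sorted(e)), 1.0))
    return g


TWO_TRIANGLES = [("a", "b"), ("a", "c"), ("b", "c"),
                 ("d", "e"), ("d", "f"), ("e", "f"), ("c", "d")]


class TestEdgeBetweenness:
    def test_bridge_between_cliques_is_nine(self):
        eb = edge_betweenness(_graph(TWO_TRIANGLES))
        assert eb[("c", "d")] == pytest.approx(9.0)

    def test_triangle_edges_share_paths(self):
        eb = edge_betweenness(_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        for e in eb:
            assert eb[e] == pytest.approx(1.0)

    def test_single_edge(self):
        eb = edge_betweenness(_graph([("a", "b")]))
        assert eb[("a", "b")] == pytest.approx(1.0)

    def test_matches_networkx_on_random_graphs(self, rng):
        for trial in range(100):
            n = int(rng.integers(3, 11))
            p = float(rng.uniform(0.2, 0.8))
            gnx = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if gnx.number_of_edges() == 0:
                continue
            edges = [(f"n{u}", f"n{v}") for u, v in gnx.edges()]
            eb = edge_betweenness(_graph(edges))
            ref = nx.edge_betweenness_centrality(gnx, normalized=False)
            for (u, v), val in ref.items():
                key = tuple(sorted((f"n{u}", f"n{v}")))
                assert eb[key] == pytest.approx(val, abs=1e-9), f"trial {trial}"

    def test_weighted_lengths_redirect_paths(self):
        # square with one long edge: paths avoid it
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        lengths = {("a", "b"): 10.0, ("b", "c"): 1.0, ("c", "d"): 1.0, ("a", "d"): 1.0}
        eb = edge_betweenness(_graph(edges, lengths=lengths))
        # even the (a, b) pair routes around the long edge (length 3 < 10)
        assert eb[("a", "b")] == pytest.approx(0.0)
        # (b, c) carries the unique shortest paths of pairs (b,c), (a,b), (b,d)
        assert eb[("b", "c")] == pytest.approx(3.0)

    def test_tree_betweenness_sums_to_total_path_length(self, rng):
        # on a tree each pair's unique path contributes 1 per edge it crosses
        for _ in range(10):
            t = nx.random_labeled_tree(int(rng.integers(3, 10)), seed=int(rng.integers(2**31)))
            edges = [(f"n{u}", f"n{v}") for u, v in t.edges()]
            eb = edge_betweenness(_graph(edges))
            total = sum(nx.shortest_path_length(t, u, v)
                        for u, v in itertools.combinations(t.nodes(), 2))
            assert sum(eb.values()) == pytest.approx(total)


class TestModularity:
    def test_single_community_is_zero(self):
        g = _graph(TWO_TRIANGLES)
        labels = {n: "all" for n in g.nodes}
        assert modularity(g, labels) == pytest.approx(0.0)

    def test_two_triangles_hand_value(self):
        g = _graph(TWO_TRIANGLES)
        labels = {n: ("L" if n in "abc" else "R") for n in g.nodes}
        assert modularity(g, labels) == pytest.approx(5 / 14)

    def test_singletons_in_clique_negative(self):
        g = _graph([("a", "b"), ("b", "c"), ("a", "c")])
        labels = {n: n for n in g.nodes}
        # e_c = 0 for all, d_c = 2 each, m = 3: Q = -3*(2/6)^2 = -1/3
        assert modularity(g, labels) == pytest.approx(-1 / 3)

    def test_empty_graph_zero(self):
        g = TransOmicsGraph()
        g.add_node("a", "metabolite")
        assert modularity(g, {"a": "x"}) == 0.0


class TestGirvanNewman:
    def test_two_triangles_bipartition(self):
        g = _graph(TWO_TRIANGLES)
        part = girvan_newman(g)
        assert part.removal_order[0] == ("c", "d")
        comms = sorted(map(tuple, part.communities().values()))
        assert comms == [("a", "b", "c"), ("d", "e", "f")]
        assert part.modularity == pytest.approx(5 / 14)

    def test_two_triangle_q_is_brute_force_maximum(self):
        # maximum over all partitions of 6 nodes, checked by Bell-set enumeration
        g = _graph(TWO_TRIANGLES)
        nodes = g.nodes
        best = -1.0
        for assignment in itertools.product(range(3), repeat=6):
            labels = dict(zip(nodes, map(str, assignment)))
            best = max(best, modularity(g, labels))
        assert girvan_newman(g).modularity == pytest.approx(best)

    def test_edgeless_graph_singletons(self):
        g = TransOmicsGraph()
        for n in "abc":
            g.add_node(n, "metabolite")
        part = girvan_newman(g)
        assert len(set(part.labels.values())) == 3
        assert part.modularity == 0.0

    def test_deterministic_removal_order(self):
        g1, g2 = _graph(TWO_TRIANGLES), _graph(TWO_TRIANGLES)
        assert girvan_newman(g1).removal_order == girvan_newman(g2).removal_order

    def test_q_at_least_trivial_partition(self, rng):
        gnx = nx.gnp_random_graph(12, 0.3, seed=7)
        g = _graph([(f"n{u}", f"n{v}") for u, v in gnx.edges()])
        part = girvan_newman(g)
        trivial = {n: "one" for n in g.nodes}
        assert part.modularity >= modularity(g, trivial) - 1e-12

    def test_planted_two_blocks_recovered(self, rng):
        hits = 0
        runs = 100
        for _ in range(runs):
            edges = []
            nodes = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    same = u[0] == v[0]
                    if rng.random() < (0.9 if same else 0.05):
                        edges.append((u, v))
            g = _graph(edges)
            if len(connected := girvan_newman(g).communities()) != 2:
                continue
            blocks = sorted(frozenset(c) for c in connected.values())
            if set(map(frozenset, [{n for n in nodes if n[0] == "a"},
                                   {n for n in nodes if n[0] == "b"}])) == set(blocks):
                hits += 1
        assert hits >= 95


class TestCommunitySummary:
    def _fixture_graph(self, counts):
        """Graph with the given number of edges per domain pair, one community."""
        g = TransOmicsGraph()
        rows = []
        idx = 0
        doms = {"mgs": "microbiome_mgs", "met": "metabolite", "phe": "phenotype"}
        for (da, db), k in counts.items():
            for _ in range(k):
                a, b = f"{da}{idx}", f"{db}{idx}x"
                g.add_node(a, doms[da])
                g.add_node(b, doms[db])
                g.add_edge(a, b, rho=0.5)
                idx += 1
        labels = {n: "C01" for n in g.nodes}
        return g, CommunityPartition(labels, 0.0, [])

    def test_printed_second_community_percentages(self):
        g, part = self._fixture_graph({("mgs", "phe"): 14, ("met", "phe"): 181,
                                       ("mgs", "met"): 75})
        s = community_summary(g, part, min_community_size=5)[0]
        assert s.n_edges == 270
        assert s.pct_by_pair[("microbiome_mgs", "phenotype")] == 5
        assert s.pct_by_pair[("metabolite", "phenotype")] == 67
        assert s.pct_by_pair[("metabolite", "microbiome_mgs")] == 28

    def test_printed_largest_community_share(self):
        g, part = self._fixture_graph({("mgs", "met"): 1040, ("mgs", "phe"): 3,
                                       ("met", "phe"): 6})
        s = community_summary(g, part, min_community_size=5)[0]
        assert s.n_edges == 1049
        assert s.pct_by_pair[("metabolite", "microbiome_mgs")] == 99.1

    def test_percentages_sum_to_hundred_before_rounding(self, rng):
        g, part = self._fixture_graph({("mgs", "met"): 17, ("met", "phe"): 5,
                                       ("mgs", "phe"): 9})
        s = community_summary(g, part, min_community_size=5)[0]
        assert sum(s.frac_by_pair.values()) == pytest.approx(1.0)

    def test_small_communities_pruned_and_empty_summary(self):
        g = TransOmicsGraph()
        g.add_node("a", "metabolite")
        g.add_node("b", "microbiome_mgs")
        g.add_edge("a", "b", rho=0.4)
        part = CommunityPartition({"a": "C01", "b": "C01"}, 0.0, [])
        assert community_summary(g, part, min_community_size=5) == []
        assert summary_table([]).empty

    def test_negative_edges_counted(self):
        g = TransOmicsGraph()
        for i in range(6):
            g.add_node(f"m{i}", "microbiome_mgs")
            g.add_node(f"e{i}", "metabolite")
            g.add_edge(f"m{i}", f"e{i}", rho=0.5 if i < 4 else -0.5)
        part = CommunityPartition({n: "C01" for n in g.nodes}, 0.0, [])
        s = community_summary(g, part, min_community_size=2)[0]
        assert (s.n_positive, s.n_negative) == (4, 2)


def test_graph_construction_contracts():
    g = TransOmicsGraph()
    g.add_node("a", "metabolite")
    with pytest.raises(ValueError):
        g.add_edge("a", "a")
    with pytest.raises(ValueError):
        g.add_edge("a", "missing")
    table = pd.DataFrame([{"feature_a": "a", "domain_a": "metabolite",
                           "feature_b": "b", "domain_b": "microbiome_mgs",
                           "rho": -0.4}])
    g2 = TransOmicsGraph.from_edge_table(table)
    assert g2.edges[("a", "b")]["length"] == pytest.approx(0.6)
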