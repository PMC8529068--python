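"""Inter-omic correlation graph and Girvan–Newman community decomposition.

Nodes are features tagged with their domain; edges are the filtered
inter-omic correlations (q < 0.1 and |rho| >= 0.3).  Edge betweenness is
the number of weighted shortest paths between all unordered node pairs
passing over an edge, with fractional credit when several shortest paths
tie; the default edge length is 1 - |rho| so stronger correlations are
shorter.  Communities are found by iteratively removing the current
highest-betweenness edge (recomputing after every removal, ties broken by
lexicographic edge id) and keeping the partition along the removal
sequence that maximises Newman–Girvan modularity on the original graph.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Edge = tuple[str, str]   # always stored sorted


def _edge(u, v) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class TransOmicsGraph:
    """Undirected node-typed graph of filtered inter-omic correlation edges."""

    domains: dict[str, str] = field(default_factory=dict)       # node -> domain
    edges: dict[Edge, dict] = field(default_factory=dict)       # edge -> {rho, length}

    def add_node(self, node: str, domain: str) -> None:
        self.domains.setdefault(node, domain)

    def add_edge(self, u: str, v: str, rho: float = 0.0, length: float | None = None) -> None:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if u not in self.domains or v not in self.domains:
            raise ValueError("add both endpoints before the edge")
        if length is None:
            length = 1.0 - abs(rho)
        self.edges[_edge(u, v)] = {"rho": float(rho), "length": float(max(length, 1e-12))}

    @classmethod
    def from_edge_table(cls, edges: pd.DataFrame, weighted: bool = True) -> "TransOmicsGraph":
        g = cls()
        for row in edges.itertuples(index=False):
            g.add_node(str(row.feature_a), str(row.domain_a))
            g.add_node(str(row.feature_b), str(row.domain_b))
            length = 1.0 - abs(float(row.rho)) if weighted else 1.0
            g.add_edge(str(row.feature_a), str(row.feature_b), rho=float(row.rho), length=length)
        return g

    @property
    def nodes(self) -> list[str]:
        return sorted(self.domains)

    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {n: {} for n in self.domains}
        for (u, v), attrs in self.edges.items():
            adj[u][v] = attrs["length"]
            adj[v][u] = attrs["length"]
        return adj

    def copy(self) -> "TransOmicsGraph":
        return TransOmicsGraph(dict(self.domains), {e: dict(a) for e, a in self.edges.items()})


# ------------------------------------------------------------- betweenness

def _brandes_component(adj: dict[str, dict[str, float]], nodes: list[str]) -> dict[Edge, float]:
    """Edge betweenness on one set of nodes (Brandes with Dijkstra).

    Returns per-edge totals over unordered node pairs (ordered-pair sums
    halved), with fractional credit for tied shortest paths.
    """
    between: dict[Edge, float] = {}
    for s in nodes:
        dist = {s: 0.0}
        sigma = {n: 0.0 for n in nodes}
        sigma[s] = 1.0
        preds: dict[str, list[str]] = {n: [] for n in nodes}
        seen: set[str] = set()
        order: list[str] = []
        heap: list[tuple[float, str]] = [(0.0, s)]
        while heap:
            d, v = heapq.heappop(heap)
            if v in seen:
                continue
            seen.add(v)
            order.append(v)
            for w, length in adj[v].items():
                nd = d + length
                old = dist.get(w)
                if old is None or nd < old - 1e-12:
                    dist[w] = nd
                    sigma[w] = sigma[v]
                    preds[w] = [v]
                    heapq.heappush(heap, (nd, w))
                elif abs(nd - old) <= 1e-12 and w not in seen:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = {n: 0.0 for n in nodes}
        for w in reversed(order):
            for v in preds[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                e = _edge(v, w)
                between[e] = between.get(e, 0.0) + c
                delta[v] += c
    return {e: val / 2.0 for e, val in between.items()}


def edge_betweenness(graph: TransOmicsGraph) -> dict[Edge, float]:
    """Weighted-shortest-path betweenness of every edge (per component)."""
    if not graph.domains:
        raise ValueError("empty graph")
    adj = graph.adjacency()
    out: dict[Edge, float] = {}
    for comp in connected_components(graph):
        if len(comp) < 2:
            continue
        out.update(_brandes_component(adj, sorted(comp)))
    for e in graph.edges:
        out.setdefault(e, 0.0)
    return out


def connected_components(graph: TransOmicsGraph) -> list[set[str]]:
    adj = graph.adjacency()
    seen: set[str] = set()
    comps = []
    for start in graph.nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    comp.add(w)
                    stack.append(w)
        comps.append(comp)
    return comps


# -------------------------------------------------------------- modularity

def modularity(graph: TransOmicsGraph, labels: dict[str, str]) -> float:
    """Newman–Girvan Q = sum_c (e_c / m - (d_c / 2m)^2) on unweighted edge counts."""
    missing = set(graph.domains) - set(labels)
    if missing:
        raise ValueError(f"partition misses node(s): {sorted(missing)[:5]}")
    m = graph.n_edges()
    if m == 0:
        return 0.0
    e_c: dict[str, int] = {}
    d_c: dict[str, int] = {}
    for (u, v) in graph.edges:
        d_c[labels[u]] = d_c.get(labels[u], 0) + 1
        d_c[labels[v]] = d_c.get(labels[v], 0) + 1
        if labels[u] == labels[v]:
            e_c[labels[u]] = e_c.get(labels[u], 0) + 1
    return float(sum(e_c.get(c, 0) / m - (d / (2 * m)) ** 2 for c, d in d_c.items()))


# ------------------------------------------------------------ Girvan–Newman

@dataclass
class CommunityPartition:
    labels: dict[str, str]             # node -> community id ("C01", ...)
    modularity: float
    removal_order: list[Edge]

    def communities(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(v) for c, v in out.items()}


def _component_labels(graph: TransOmicsGraph) -> dict[str, str]:
    comps = sorted(connected_components(graph), key=lambda c: (-len(c), min(c)))
    labels = {}
    for i, comp in enumerate(comps):
        for node in comp:
            labels[node] = f"C{i + 1:02d}"
    return labels


def girvan_newman(graph: TransOmicsGraph) -> CommunityPartition:
    """Edge-betweenness community decomposition with max-modularity cut selection.

    The highest-betweenness edge is removed and betweenness recomputed each
    round (restricted to the component the removal touched) until no edges
    remain; every partition at which the component count grew is a
    candidate, and the one maximising modularity on the original graph is
    returned (earliest wins on ties).  Equal betweenness values are broken
    by lexicographic edge id, making the removal order deterministic.
    """
    if not graph.domains:
        raise ValueError("empty graph")
    original = graph.copy()
    work = graph.copy()

    candidates: list[dict[str, str]] = [_component_labels(work)]
    removal_order: list[Edge] = []

    # per-component cached betweenness, keyed by frozenset of nodes
    comp_of: dict[frozenset, dict[Edge, float]] = {}
    for comp in connected_components(work):
        sub = frozenset(comp)
        if len(comp) > 1:
            comp_of[sub] = _brandes_component(work.adjacency(), sorted(comp))

    n_comps = len(set(candidates[0].values()))
    while work.n_edges() > 0:
        best_edge, best_val = None, -1.0
        for table in comp_of.values():
            for e, val in table.items():
                if val > best_val + 1e-12 or (abs(val - best_val) <= 1e-12 and
                                              (best_edge is None or e < best_edge)):
                    best_edge, best_val = e, val
        assert best_edge is not None
        # find and drop the component containing the edge
        home = next(k for k in comp_of if best_edge[0] in k)
        del comp_of[home]
        del work.edges[best_edge]
        removal_order.append(best_edge)
        adj = work.adjacency()
        # recompute betweenness for the (1 or 2) components replacing `home`
        remaining = set(home)
        new_comps = []
        while remaining:
            start = next(iter(remaining))
            comp = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w in remaining and w not in comp:
                        comp.add(w)
                        stack.append(w)
            remaining -= comp
            new_comps.append(comp)
        for comp in new_comps:
            if len(comp) > 1 and any(adj[v] for v in comp):
                comp_of[frozenset(comp)] = _brandes_component(adj, sorted(comp))
        new_n = sum(1 for _ in connected_components(work))
        if new_n > n_comps:
            candidates.append(_component_labels(work))
            n_comps = new_n

    scored = [(modularity(original, labels), i, labels) for i, labels in enumerate(candidates)]
    best_q, _, best_labels = max(scored, key=lambda t: (t[0], -t[1]))
    return CommunityPartition(best_labels, float(best_q), removal_order)


# ----------------------------------------------------------------- summary

@dataclass
class CommunitySummary:
    community: str
    n_nodes: int
    nodes_by_domain: dict[str, int]
    n_edges: int
    edges_by_pair: dict[tuple[str, str], int]
    pct_by_pair: dict[tuple[str, str], float]        # display-rounded
    frac_by_pair: dict[tuple[str, str], float]       # exact fractions
    n_positive: int
    n_negative: int


def community_summary(graph: TransOmicsGraph, partition: CommunityPartition,
                      min_community_size: int = 5) -> list[CommunitySummary]:
    """Per-community node/edge composition by domain pair, pruning small communities.

    Percentages are of that community's own edges; display rounding is one
    decimal place when the community holds at least 1000 edges and the
    nearest integer otherwise.  Communities below ``min_community_size``
    nodes are pruned.
    """
    members = partition.communities()
    out: list[CommunitySummary] = []
    for comm in sorted(members, key=lambda c: (-len(members[c]), c)):
        nodes = members[comm]
        if len(nodes) < min_community_size:
            continue
        node_set = set(nodes)
        by_dom: dict[str, int] = {}
        for v in nodes:
            d = graph.domains[v]
            by_dom[d] = by_dom.get(d, 0) + 1
        edges = [(e, a) for e, a in graph.edges.items()
                 if e[0] in node_set and e[1] in node_set]
        by_pair: dict[tuple[str, str], int] = {}
        pos = neg = 0
        for (u, v), attrs in edges:
            pair = tuple(sorted((graph.domains[u], graph.domains[v])))
            by_pair[pair] = by_pair.get(pair, 0) + 1
            if attrs["rho"] >= 0:
                pos += 1
            else:
                neg += 1
        total = len(edges)
        frac = {p: c / total for p, c in by_pair.items()} if total else {}
        if total >= 1000:
            pct = {p: round(100 * f, 1) for p, f in frac.items()}
        else:
            pct = {p: int(round(100 * f)) for p, f in frac.items()}
        out.append(CommunitySummary(comm, len(nodes), by_dom, total, by_pair,
                                    pct, frac, pos, neg))
    return out


def summary_table(summaries: list[CommunitySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for pair, count in sorted(s.edges_by_pair.items()):
            rows.append({
                "community": s.community, "n_nodes": s.n_nodes, "n_edges": s.n_edges,
                "domain_pair": f"{pair[0]}|{pair[1]}", "edges": count,
                "pct": s.pct_by_pair[pair],
                "n_positive": s.n_positive, "n_negative": s.n_negative,
            })
    return pd.DataFrame(rows)


def to_networkx(graph: TransOmicsGraph):
    """Export as a networkx Graph (used for GraphML serialisation)."""
    import networkx as nx

    g = nx.Graph()
    for node, dom in graph.domains.items():
        g.add_node(node, domain=dom)
    for (u, v), attrs in graph.edges.items():
        g.add_edge(u, v, rho=attrs["rho"], length=attrs["length"],
                   sign="positive" if attrs["rho"] >= 0 else "negative")
    return g
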