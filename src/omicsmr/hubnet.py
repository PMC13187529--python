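"""Hub-gene scoring on a protein-interaction graph.

Implements the five node-centrality scores commonly used to nominate hub
genes from a PPI network — maximal clique centrality (MCC), maximum
neighborhood component (MNC), degree, reciprocal-distance closeness and
radiality — and the closed top-k intersection across all five rankings.
Ties that span the k-th rank are all included, so the result does not
depend on input ordering.
"""

from __future__ import annotations

from math import factorial

import networkx as nx
import pandas as pd

METHODS = ("mcc", "mnc", "degree", "closeness", "radiality")


def as_graph(edges_or_graph) -> nx.Graph:
    """Validate and return a simple undirected graph.

    Self-loops and duplicate edges are rejected rather than cleaned.
    """
    if isinstance(edges_or_graph, nx.Graph):
        g = edges_or_graph
        if any(u == v for u, v in g.edges):
            raise ValueError("graph contains self-loops")
        if g.is_directed() or g.is_multigraph():
            raise ValueError("graph must be simple and undirected")
        return g
    g = nx.Graph()
    seen = set()
    for u, v in edges_or_graph:
        if u == v:
            raise ValueError(f"self-loop at node {u!r}")
        key = frozenset((u, v))
        if key in seen:
            raise ValueError(f"duplicate edge {u!r}-{v!r}")
        seen.add(key)
        g.add_edge(u, v)
    return g


def mcc(graph) -> dict:
    """Maximal clique centrality: sum over maximal cliques containing v of
    (|C| - 1)!.  An isolated node's sole maximal clique is itself (score 1)."""
    g = as_graph(graph)
    scores = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        w = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def mnc(graph) -> dict:
    """Maximum neighborhood component: size of the largest connected
    component of the subgraph induced by v's neighbors (v excluded)."""
    g = as_graph(graph)
    scores = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            scores[v] = 0
            continue
        sub = g.subgraph(nbrs)
        scores[v] = max(len(c) for c in nx.connected_components(sub))
    return scores


def degree(graph) -> dict:
    g = as_graph(graph)
    return dict(g.degree())


def closeness(graph) -> dict:
    """Reciprocal-distance closeness: sum of 1/d(v, u), unreachable pairs
    contribute 0 (the cytoHubba form; harmonic centrality)."""
    g = as_graph(graph)
    return {v: float(c) for v, c in nx.harmonic_centrality(g).items()}


def radiality(graph) -> dict:
    """Per connected component: sum over reachable u of
    (diameter + 1 - d(v, u)) / (n_component - 1); isolated nodes score 0."""
    g = as_graph(graph)
    scores = {}
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) == 1:
            scores[comp[0]] = 0.0
            continue
        sub = g.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        for v in comp:
            total = sum(diam + 1 - d for u, d in dist[v].items() if u != v)
            scores[v] = total / (len(comp) - 1)
    return scores


def hub_scores(graph) -> pd.DataFrame:
    """All five centralities as one node-indexed table."""
    g = as_graph(graph)
    table = pd.DataFrame(
        {
            "mcc": pd.Series(mcc(g), dtype=float),
            "mnc": pd.Series(mnc(g), dtype=float),
            "degree": pd.Series(degree(g), dtype=float),
            "closeness": pd.Series(closeness(g), dtype=float),
            "radiality": pd.Series(radiality(g), dtype=float),
        }
    )
    return table.sort_index()


def top_k(scores: pd.Series, k: int) -> list:
    """Closed top-k: rank by (score desc, node id asc) and include every
    node tied with the k-th score."""
    if k <= 0:
        return []
    ordered = scores.sort_index().sort_values(ascending=False, kind="mergesort")
    if k >= len(ordered):
        return list(ordered.index)
    cutoff = ordered.iloc[k - 1]
    return list(ordered[ordered >= cutoff].index)


def hub_intersection(scores: pd.DataFrame, k: int = 30):
    """Intersect the closed top-k lists of all five methods.

    Returns ``(sorted node list, per-method top-k dict)``.
    """
    if k > len(scores):
        raise ValueError("k exceeds the node count")
    lists = {m: top_k(scores[m], k) for m in METHODS}
    inter = set(scores.index)
    for nodes in lists.values():
        inter &= set(nodes)
    return sorted(inter), lists
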