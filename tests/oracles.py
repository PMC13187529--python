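"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own implementations: centralities
are computed by exhaustive subset enumeration and BFS, topological
overlap by a triple loop, clumping audited pairwise, and the weighted
least-squares equivalence via statsmodels.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_mcc(g: nx.Graph) -> dict:
    nodes = list(g.nodes)
    scores = {v: 0 for v in nodes}
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not all(g.has_edge(u, v) for u, v in itertools.combinations(sub, 2)):
                continue
            s = set(sub)
            if any(
                all(g.has_edge(w, u) for u in sub) for w in nodes if w not in s
            ):
                continue  # extendable, hence not maximal
            for v in sub:
                scores[v] += math.factorial(r - 1)
    return scores


def brute_mnc(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        best = 0
        for r in range(1, len(nbrs) + 1):
            for sub in itertools.combinations(nbrs, r):
                if nx.is_connected(g.subgraph(sub)):
                    best = max(best, r)
        out[v] = best
    return out


def brute_closeness_radiality(g: nx.Graph):
    clo = {v: 0.0 for v in g.nodes}
    rad = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            continue
        sub = g.subgraph(comp)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in dist.values())
        for v in comp:
            clo[v] = sum(1.0 / d for u, d in dist[v].items() if u != v)
            rad[v] = sum(diam + 1 - d for u, d in dist[v].items() if u != v) / (
                len(comp) - 1
            )
    return clo, rad


def brute_tom(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    k = a.sum(axis=0) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def all_graphs(n: int):
    """Every labelled simple graph on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for b, (u, v) in enumerate(pairs):
            if mask >> b & 1:
                g.add_edge(u, v)
        yield g


def clump_violations(kept, ld, positions, r2_threshold, window_kb) -> list:
    """Pairs of retained SNPs that violate the clumping rule."""
    bad = []
    for a, b in itertools.combinations(kept, 2):
        if abs(positions[a] - positions[b]) <= window_kb * 1000 and ld.r2(a, b) > r2_threshold:
            bad.append((a, b))
    return bad
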