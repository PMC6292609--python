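"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive path enumeration, subset
enumeration, pair counting — and shares no code with the package. Only ever
run on tiny graphs (<= 8 nodes) or short score vectors.
"""

from itertools import combinations, permutations
from math import comb, factorial

import networkx as nx
import numpy as np


def all_shortest_paths_between(g, s, t):
    """Every shortest s-t path, by exhaustive simple-path enumeration."""
    paths = [p for p in nx.all_simple_paths(g, s, t)]
    if s == t or not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def betweenness_brute(g):
    """Normalized betweenness by enumerating every shortest path."""
    n = g.number_of_nodes()
    bc = {v: 0.0 for v in g}
    for s, t in combinations(g.nodes, 2):
        paths = all_shortest_paths_between(g, s, t)
        if not paths:
            continue
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: bc[v] * scale for v in g}


def load_brute(g):
    """Normalized load centrality by explicit unit-packet forwarding.

    A unit packet travels from s to t; at each node it splits equally among
    the neighbours lying on shortest paths onward to t. A node's load over the
    pair is the packet mass passing through it (endpoints excluded).
    """
    n = g.number_of_nodes()
    load = {v: 0.0 for v in g}
    for s in g:
        for t in g:
            if s == t:
                continue
            try:
                dist_t = nx.single_source_shortest_path_length(g, t)
            except nx.NetworkXError:
                continue
            if s not in dist_t:
                continue
            mass = {s: 1.0}
            d = dist_t[s]
            while d > 0:
                nxt = {}
                for v, m in mass.items():
                    fwd = [u for u in g.adj[v] if dist_t.get(u, np.inf) == dist_t[v] - 1]
                    for u in fwd:
                        nxt[u] = nxt.get(u, 0.0) + m / len(fwd)
                for v, m in nxt.items():
                    if v not in (s, t):
                        load[v] += m
                mass = nxt
                d -= 1
    scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: load[v] * scale for v in g}


def closeness_brute(g):
    """Closeness with the per-component (n_c - 1)/(n - 1) rescaling."""
    n = g.number_of_nodes()
    out = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(d for d in dist.values())
        reach = len(dist) - 1
        if total == 0 or reach == 0 or n <= 1:
            out[v] = 0.0
        else:
            out[v] = (reach / total) * (reach / (n - 1))
    return out


def harmonic_brute(g):
    """Sum of reciprocal distances, divided by n - 1."""
    n = g.number_of_nodes()
    out = {}
    for v in g:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(1.0 / d for u, d in dist.items() if u != v)
        out[v] = total / (n - 1) if n > 1 else 0.0
    return out


def degree_centrality_brute(g):
    n = g.number_of_nodes()
    return {v: g.degree[v] / (n - 1) if n > 1 else 0.0 for v in g}


def clustering_brute(g):
    out = {}
    for v in g:
        nbrs = list(g.adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = links / comb(k, 2)
    return out


def ecc_brute(g):
    """Edge-clustering-coefficient centrality by enumerating node triples."""
    out = {}
    for v in g:
        total = 0.0
        for u in g.adj[v]:
            denom = min(g.degree[u] - 1, g.degree[v] - 1)
            if denom <= 0:
                continue
            z = sum(1 for w in g if w not in (u, v) and g.has_edge(w, u) and g.has_edge(w, v))
            total += (z + 1) / denom
        out[v] = total
    return out


def clique_number_brute(g):
    """Largest clique containing each node, by subset enumeration."""
    nodes = list(g.nodes)
    out = {v: 1 for v in nodes}
    for r in range(2, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in combinations(sub, 2)):
                for v in sub:
                    out[v] = max(out[v], r)
    return out


def egonet_counts_brute(g, v):
    """(within, out) edge counts for the closed egonet of v by direct
    classification of every graph edge."""
    ego = set(g.adj[v]) | {v}
    within = sum(1 for a, b in g.edges if a in ego and b in ego)
    out = sum(1 for a, b in g.edges if (a in ego) != (b in ego))
    return within, out


def subgraph_centrality_series(g, kmax=30):
    """Truncated matrix-power series sum_k (A^k)_vv / k!."""
    nodes = list(g.nodes)
    a = (nx.to_numpy_array(g, nodelist=nodes) > 0).astype(float)
    acc = np.eye(len(nodes))
    total = np.eye(len(nodes)).copy()
    for k in range(1, kmax + 1):
        acc = acc @ a
        total += acc / factorial(k)
    return {v: total[i, i] for i, v in enumerate(nodes)}


def auroc_pairs(scores, truth):
    """AUROC as the pair-counting rank statistic (ties count one half)."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def ranksum_exact(a, b):
    """Exact one-sided rank-sum p-value P(rank-sum of group a >= observed)
    by enumerating every assignment of the pooled values to group a."""
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, float)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    # midranks for ties
    order = np.sort(pooled)
    rank_of = {}
    for val in np.unique(pooled):
        idx = np.flatnonzero(order == val) + 1
        rank_of[val] = idx.mean()
    ranks = np.array([rank_of[v] for v in pooled])
    na = len(a)
    observed = ranks[:na].sum()
    hits = total = 0
    for sub in combinations(range(len(pooled)), na):
        total += 1
        if ranks[list(sub)].sum() >= observed - 1e-12:
            hits += 1
    return hits / total
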