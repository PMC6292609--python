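"""Node centrality and related topological measures.

Implements the twelve classical centrality measures used for
centrality–lethality analysis (closeness, betweenness, degree, eigenvector,
subgraph, information, random-walk betweenness, load, harmonic, reaching,
edge-clustering-coefficient centrality and PageRank) plus four further node
properties (clique number, local clustering coefficient, number of biconnected
components containing the node, and weighted degree).

All measures are computed on the unweighted topology except ``wdegree``, which
is the sum of incident association weights. Measures that are only defined on
a connected graph (information centrality, current-flow betweenness,
eigenvector centrality) are computed within each connected component;
singleton components receive 0.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

#: the classical twelve, in canonical column order
CENTRALITY12 = [
    "closeness_centrality",
    "betweenness_centrality",
    "degree_centrality",
    "eigenvector_centrality",
    "subgraph_centrality",
    "information_centrality",
    "random_walk_betweenness_centrality",
    "load_centrality",
    "harmonic_centrality",
    "reaching_centrality",
    "edge_clustering_coefficient_centrality",
    "pagerank",
]

#: the twelve plus clique number and clustering coefficient
NETWORK14 = CENTRALITY12 + ["clique_number", "clustering_coefficient"]

#: extra node properties appearing in the combined network feature set
EXTRA_PROPERTIES = ["clique_number", "clustering_coefficient", "biconnected_components", "wdegree"]

#: conventional small feature set used as a baseline in earlier studies
NAIVE_BASELINE = [
    "degree_centrality",
    "closeness_centrality",
    "clustering_coefficient",
    "betweenness_centrality",
]

ALL_MEASURES = CENTRALITY12 + EXTRA_PROPERTIES

MEASURE_SETS = {
    "centrality12": CENTRALITY12,
    "network14": NETWORK14,
    "naive_baseline": NAIVE_BASELINE,
    "all": ALL_MEASURES,
}

_PAGERANK_DAMPING = 0.85
_POWER_TOL = 1e-8
_POWER_MAX_ITER = 1000


def _graph_of(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.graph


def _per_component(g: nx.Graph, func, min_size: int = 2) -> dict:
    """Apply ``func`` to each connected component of at least ``min_size`` nodes;
    nodes in smaller components get 0."""
    out = {v: 0.0 for v in g}
    for comp in nx.connected_components(g):
        if len(comp) >= min_size:
            out.update(func(g.subgraph(comp)))
    return out


def edge_clustering_coefficient_centrality(net) -> dict:
    """NC(v) = sum over neighbours u of (z_uv + 1) / min(deg u - 1, deg v - 1),
    where z_uv is the number of triangles containing edge (u, v). Edges whose
    denominator is <= 0 contribute 0, which keeps leaves finite."""
    g = _graph_of(net)
    adj = {v: set(g.adj[v]) for v in g}
    nc = {}
    for v in g:
        total = 0.0
        dv = len(adj[v])
        for u in adj[v]:
            denom = min(len(adj[u]) - 1, dv - 1)
            if denom <= 0:
                continue
            z = len(adj[u] & adj[v])
            total += (z + 1) / denom
        nc[v] = total
    return nc


def local_reaching_centrality(net) -> dict:
    """Fraction of other nodes reachable from v: |{u != v : d(v, u) < inf}| / (N - 1)."""
    g = _graph_of(net)
    n = g.number_of_nodes()
    if n <= 1:
        return {v: 0.0 for v in g}
    out = {}
    for comp in nx.connected_components(g):
        frac = (len(comp) - 1) / (n - 1)
        for v in comp:
            out[v] = frac
    return out


def node_clique_number(net) -> dict:
    """Size of the largest maximal clique containing each node (isolated node -> 1)."""
    g = _graph_of(net)
    out = {v: 1 for v in g}
    for clique in nx.find_cliques(g):
        k = len(clique)
        for v in clique:
            if k > out[v]:
                out[v] = k
    return out


def biconnected_component_count(net) -> dict:
    """Number of biconnected components each node belongs to.

    Articulation points get > 1; nodes of degree >= 1 inside one block get 1;
    isolated nodes get 0 (they belong to no edge-containing block).
    """
    g = _graph_of(net)
    out = {v: 0 for v in g}
    for comp in nx.biconnected_components(g):
        for v in comp:
            out[v] += 1
    return out


def weighted_degree(net) -> dict:
    g = _graph_of(net)
    return {v: float(d) for v, d in g.degree(weight="weight")}


def _eigenvector(g: nx.Graph) -> dict:
    def one(sub):
        return nx.eigenvector_centrality(sub, max_iter=_POWER_MAX_ITER, tol=_POWER_TOL)

    return _per_component(g, one)


def _information(g: nx.Graph) -> dict:
    return _per_component(g, nx.current_flow_closeness_centrality)


def _current_flow_betweenness(g: nx.Graph) -> dict:
    # normalisation divides by (n-1)(n-2); components below 3 nodes carry no flow
    return _per_component(g, nx.current_flow_betweenness_centrality, min_size=3)


def _subgraph(g: nx.Graph) -> dict:
    # strip weights: the adjacency spectrum must be topological
    bare = nx.Graph()
    bare.add_nodes_from(g)
    bare.add_edges_from(g.edges)
    return nx.subgraph_centrality(bare)


def _harmonic(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    if n <= 1:
        return {v: 0.0 for v in g}
    raw = nx.harmonic_centrality(g)
    return {v: x / (n - 1) for v, x in raw.items()}


def _degree_centrality(g: nx.Graph) -> dict:
    if g.number_of_nodes() <= 1:
        return {v: 0.0 for v in g}
    return nx.degree_centrality(g)


_DISPATCH = {
    "closeness_centrality": nx.closeness_centrality,
    "betweenness_centrality": lambda g: nx.betweenness_centrality(g, normalized=True),
    "degree_centrality": _degree_centrality,
    "eigenvector_centrality": _eigenvector,
    "subgraph_centrality": _subgraph,
    "information_centrality": _information,
    "random_walk_betweenness_centrality": _current_flow_betweenness,
    "load_centrality": lambda g: nx.load_centrality(g, normalized=True),
    "harmonic_centrality": _harmonic,
    "reaching_centrality": local_reaching_centrality,
    "edge_clustering_coefficient_centrality": edge_clustering_coefficient_centrality,
    "pagerank": lambda g: nx.pagerank(
        g, alpha=_PAGERANK_DAMPING, tol=_POWER_TOL, max_iter=_POWER_MAX_ITER, weight=None
    ),
    "clique_number": node_clique_number,
    "clustering_coefficient": nx.clustering,
    "biconnected_components": biconnected_component_count,
    "wdegree": weighted_degree,
}


def compute_measure(net, measure: str) -> pd.Series:
    """Compute one named measure for every node of the network.

    Returns a float Series indexed by node. Unknown names raise ``ValueError``
    listing the valid measure names.
    """
    if measure not in _DISPATCH:
        raise ValueError(
            f"unknown measure {measure!r}; valid names: {', '.join(sorted(_DISPATCH))}"
        )
    g = _graph_of(net)
    values = _DISPATCH[measure](g)
    s = pd.Series(values, dtype=float, name=measure)
    if not s.empty:
        s = s.reindex(list(g.nodes))
        if not s.map(math.isfinite).all():
            raise ValueError(f"{measure}: non-finite value produced")
    return s


def compute_all(net, measure_set) -> pd.DataFrame:
    """Compute a set of measures as a node x measure DataFrame.

    ``measure_set`` is either a named set ("centrality12", "network14",
    "naive_baseline", "all") or an explicit list of measure names. Columns
    follow the canonical order of the requested set.
    """
    if isinstance(measure_set, str):
        if measure_set not in MEASURE_SETS:
            raise ValueError(
                f"unknown measure set {measure_set!r}; valid: {', '.join(MEASURE_SETS)}"
            )
        names = MEASURE_SETS[measure_set]
    else:
        names = list(measure_set)
        if not names:
            raise ValueError("empty measure set")
    g = _graph_of(net)
    df = pd.DataFrame(index=list(g.nodes))
    for name in names:
        df[name] = compute_measure(net, name)
    return df
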