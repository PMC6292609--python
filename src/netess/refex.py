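"""Recursive structural feature extraction on association networks.

Starting from six base features of each node — degree, weighted degree, and
the edge counts (plain and weight-summed) inside and leaving the node's closed
egonet — the extractor repeatedly forms the sum and the mean of every retained
feature over each node's neighbours ("regional" features), then prunes
near-duplicate features by comparing vertically log-binned values. The
retained catalogue is a deterministic structural fingerprint of the network,
and any catalogue can be re-evaluated on any other network, which is what
makes these features transferable across organisms of very different size.

Feature names form a small grammar::

    base      ::= degree | wdegree | ego_within | ego_out | wego_within | wego_out
    composite ::= "sum(" name ")" | "mean(" name ")"

The recursion depth of a name is its nesting count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .catalogue import FeatureCatalogue, recursion_depth

BASE_FEATURES = ["degree", "wdegree", "ego_within", "ego_out", "wego_within", "wego_out"]

_BASE_CATEGORY = {
    "degree": "local",
    "wdegree": "local",
    "ego_within": "egonet",
    "ego_out": "egonet",
    "wego_within": "egonet",
    "wego_out": "egonet",
}


def parse_feature(name: str) -> tuple[str, list]:
    """Parse a canonical feature name into (base, [ops outermost-first]).

    Raises ``ValueError`` for names outside the grammar, naming the offender.
    """
    ops = []
    rest = name
    while True:
        if rest in _BASE_CATEGORY:
            return rest, ops
        if rest.startswith("sum(") and rest.endswith(")"):
            ops.append("sum")
            rest = rest[4:-1]
        elif rest.startswith("mean(") and rest.endswith(")"):
            ops.append("mean")
            rest = rest[5:-1]
        else:
            raise ValueError(f"unparseable feature name {name!r}")


def feature_category(name: str) -> str:
    base, ops = parse_feature(name)
    return "regional" if ops else _BASE_CATEGORY[base]


def _catalogue(names) -> FeatureCatalogue:
    return FeatureCatalogue(list(names), {n: feature_category(n) for n in names})


@dataclass
class PruneParams:
    """Parameters of the binning/pruning schedule.

    ``bin_fraction`` is the fraction of still-unassigned nodes placed in each
    successive bin of the vertical logarithmic binning. The similarity
    threshold ``s`` grows with the iteration number (0-based) via
    ``threshold_schedule``, so later, deeper features must differ more to be
    kept — this is what makes the recursion terminate.
    """

    bin_fraction: float = 0.5
    threshold_schedule: object = field(default=None)
    max_iterations: int = 10

    def __post_init__(self):
        if not 0.0 < self.bin_fraction < 1.0:
            raise ValueError("bin_fraction must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.threshold_schedule is None:
            self.threshold_schedule = lambda i: i

    def s(self, iteration: int) -> int:
        v = int(self.threshold_schedule(iteration))
        if v < 0:
            raise ValueError("similarity threshold must be nonnegative")
        return v


def base_features(net) -> pd.DataFrame:
    """Compute the six base features for every node.

    ``ego_within`` counts edges with both endpoints in the closed egonet of v
    (v plus its neighbours); ``ego_out`` counts edges with exactly one endpoint
    inside. The ``w``-prefixed columns sum association weights over the same
    edge sets.
    """
    g = net if isinstance(net, nx.Graph) else net.graph
    nodes = list(g.nodes)
    adj = {v: set(g.adj[v]) for v in nodes}
    rows = np.zeros((len(nodes), 6))
    for i, v in enumerate(nodes):
        ego = adj[v] | {v}
        within = wwithin = out = wout = 0.0
        for u in ego:
            for nb, data in g.adj[u].items():
                w = data["weight"]
                if nb in ego:
                    within += 0.5  # each within-edge visited from both ends
                    wwithin += 0.5 * w
                else:
                    out += 1.0
                    wout += w
        rows[i] = (
            len(adj[v]),
            sum(g.adj[v][u]["weight"] for u in adj[v]),
            within,
            out,
            wwithin,
            wout,
        )
    return pd.DataFrame(rows, index=nodes, columns=BASE_FEATURES)


def vertical_log_bin(values, p: float) -> np.ndarray:
    """Vertical logarithmic binning.

    Repeatedly assigns the ``ceil(p * remaining)`` smallest-valued unassigned
    nodes to the next bin (starting at 0); all nodes tied with the boundary
    value join the same bin. Returns integer bins aligned with the input order.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    n = len(values)
    bins = np.empty(n, dtype=int)
    if n == 0:
        return bins
    order = np.argsort(values, kind="stable")
    pos = 0
    b = 0
    while pos < n:
        take = math.ceil(p * (n - pos))
        cut = pos + take
        # extend over ties with the boundary value
        while cut < n and values[order[cut]] == values[order[cut - 1]]:
            cut += 1
        bins[order[pos:cut]] = b
        pos = cut
        b += 1
    return bins


def prune_features(matrix: pd.DataFrame, s: int, p: float) -> FeatureCatalogue:
    """Collapse near-duplicate features, keeping one representative per group.

    Features are vertically log-binned column by column; two features are
    linked when their bins differ by at most ``s`` at every node, and each
    connected group of linked features keeps the representative with the
    smallest recursion depth (ties broken by name order).
    """
    if matrix.shape[1] == 0:
        return _catalogue([])
    cols = list(matrix.columns)
    binned = np.column_stack([vertical_log_bin(matrix[c].to_numpy(), p) for c in cols])
    fg = nx.Graph()
    fg.add_nodes_from(cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.max(np.abs(binned[:, i] - binned[:, j]), initial=0) <= s:
                fg.add_edge(cols[i], cols[j])
    reps = [
        min(comp, key=lambda c: (recursion_depth(c), c))
        for comp in nx.connected_components(fg)
    ]
    reps.sort(key=lambda c: (recursion_depth(c), c))
    return _catalogue(reps)


def _neighbour_aggregate(g, values: pd.Series, op: str) -> pd.Series:
    """Sum or mean of a node feature over each node's (open) neighbourhood;
    empty neighbourhood gives 0 for both."""
    vals = values.to_dict()
    out = {}
    for v in g.nodes:
        nbrs = list(g.adj[v])
        if not nbrs:
            out[v] = 0.0
        else:
            total = sum(vals[u] for u in nbrs)
            out[v] = total if op == "sum" else total / len(nbrs)
    return pd.Series(out, dtype=float).reindex(values.index)


def extract_refex(net, params: PruneParams | None = None) -> tuple[pd.DataFrame, FeatureCatalogue]:
    """Run the full recursive extraction on one network.

    Returns the node x feature matrix of retained features and the matching
    catalogue. Entirely deterministic: two runs with identical input and
    parameters produce identical output.
    """
    if params is None:
        params = PruneParams()
    g = net if isinstance(net, nx.Graph) else net.graph
    values = base_features(net)
    retained = prune_features(values, s=params.s(0), p=params.bin_fraction)
    values = values[retained.names]
    for it in range(1, params.max_iterations + 1):
        candidates = values.copy()
        for name in retained.names:
            for op in ("sum", "mean"):
                new_name = f"{op}({name})"
                if new_name not in candidates.columns:
                    candidates[new_name] = _neighbour_aggregate(g, values[name], op)
        new_retained = prune_features(candidates, s=params.s(it), p=params.bin_fraction)
        novel = set(new_retained.names) - set(retained.names)
        retained = new_retained
        values = candidates[retained.names]
        if not novel:
            break
    order = sorted(retained.names, key=lambda c: (recursion_depth(c), c))
    return values[order], _catalogue(order)


def compute_named(net, catalogue) -> pd.DataFrame:
    """Evaluate an arbitrary catalogue of recursive feature names on a network.

    This ignores what pruning would have retained locally — the point is to
    evaluate a catalogue discovered elsewhere (e.g. the union across a cohort)
    on this network. Column order follows the catalogue.
    """
    g = net if isinstance(net, nx.Graph) else net.graph
    names = list(catalogue)
    for n in names:
        parse_feature(n)  # raises on bad names before any work
    base = base_features(net)
    cache: dict[str, pd.Series] = {c: base[c] for c in base.columns}

    def evaluate(name: str) -> pd.Series:
        if name in cache:
            return cache[name]
        if name.startswith("sum("):
            op, inner = "sum", name[4:-1]
        else:
            op, inner = "mean", name[5:-1]
        result = _neighbour_aggregate(g, evaluate(inner), op)
        cache[name] = result
        return result

    return pd.DataFrame({n: evaluate(n) for n in names}, index=base.index)


def union_catalogue(catalogues) -> FeatureCatalogue:
    """De-duplicated union of catalogues, ordered by (recursion depth, name)."""
    catalogues = list(catalogues)
    if not catalogues:
        raise ValueError("need at least one catalogue")
    names = set()
    for cat in catalogues:
        names.update(cat)
    order = sorted(names, key=lambda c: (recursion_depth(c), c))
    return _catalogue(order)


def synthetic_reference_catalogue(size: int) -> FeatureCatalogue:
    """A synthetic stand-in for a published recursive-feature name list.

    Enumerates grammar-valid names breadth-first by (depth, name) and returns
    the first ``size``, excluding the bare weighted-degree base so that the
    list is disjoint from the separately counted node properties (clique
    number, clustering coefficient, biconnected components, weighted degree),
    as the published union list evidently was. Use only where a fixed-size
    catalogue is needed for bookkeeping; real analyses use catalogues
    extracted from networks.
    """
    bases = [b for b in BASE_FEATURES if b != "wdegree"]
    frontier = sorted(bases)
    names: list[str] = []
    while len(names) < size:
        names.extend(frontier)
        frontier = sorted(
            [f"{op}({n})" for n in frontier for op in ("mean", "sum")]
        )
    return _catalogue(names[:size])
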