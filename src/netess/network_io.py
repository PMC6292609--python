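"""Reading and validating organism association networks and essentiality labels.

Networks come as STRING ``protein.links``-style text: one header line, then
whitespace-separated rows ``protein1 protein2 combined_score`` with the score
an integer in [0, 1000]. Edge weights are stored as ``score / 1000`` so that
weighted degree is bounded and comparable across organisms before scaling.
Essentiality labels come as two-column TSV (``gene_id``, ``essential`` or
``non-essential``); downstream feature matrices only ever see genes that are
present in the network, mirroring the usual restriction of curated essentiality
calls to the interactome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

ESSENTIAL = "essential"
NON_ESSENTIAL = "non-essential"
_VALID_LABELS = frozenset({ESSENTIAL, NON_ESSENTIAL})


class ParseError(ValueError):
    """A malformed row in a network or label file."""


class ConsistencyError(ValueError):
    """Contradictory duplicate entries within one file."""


@dataclass
class InteractionNetwork:
    """One organism's undirected weighted protein-association graph.

    Invariants: simple graph (no self-loops, no parallel edges); every edge
    weight lies in (0, 1]; the node set is the union of edge endpoints plus any
    explicitly declared isolated nodes.
    """

    organism_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u, v) -> float:
        return self.graph.edges[u, v]["weight"]

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ConsistencyError(f"{self.organism_id}: self-loop present")
        for u, v, w in self.graph.edges(data="weight"):
            if not (0.0 < w <= 1.0):
                raise ConsistencyError(
                    f"{self.organism_id}: weight {w!r} on edge ({u}, {v}) outside (0, 1]"
                )


@dataclass
class EssentialityLabels:
    """Binary essential / non-essential calls for one organism's genes."""

    organism_id: str
    labels: dict = field(default_factory=dict)  # gene_id -> bool (True = essential)

    @property
    def genes(self) -> set:
        return set(self.labels)

    @property
    def n_essential(self) -> int:
        return sum(self.labels.values())

    @property
    def n_non_essential(self) -> int:
        return len(self.labels) - self.n_essential

    def __len__(self) -> int:
        return len(self.labels)


def read_string_edgelist(path, score_threshold: int = 0, organism_id: str | None = None) -> InteractionNetwork:
    """Read a STRING protein.links-dialect edge list.

    The first line is a header and skipped. Symmetric duplicate rows (A B s /
    B A s) collapse to one undirected edge; duplicates with disagreeing scores
    raise :class:`ConsistencyError`. Rows with ``combined_score`` below
    ``score_threshold`` are dropped before the graph is built, so a node whose
    every edge falls below threshold does not appear at all. Self-loops are
    dropped with a warning.
    """
    if not 0 <= score_threshold <= 1000:
        raise ValueError(f"score_threshold must be in [0, 1000], got {score_threshold}")
    path = str(path)
    if organism_id is None:
        organism_id = path.rsplit("/", 1)[-1].split(".")[0]
    g = nx.Graph()
    seen: dict[frozenset, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields, got {len(tokens)}")
            a, b, raw = tokens
            try:
                score = int(raw)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer score {raw!r}") from None
            if not 0 <= score <= 1000:
                raise ParseError(f"{path}: line {lineno}: score {score} outside [0, 1000]")
            if a == b:
                logger.warning("%s: line %d: dropping self-loop on %s", path, lineno, a)
                continue
            key = frozenset((a, b))
            if key in seen:
                if seen[key] != score:
                    raise ConsistencyError(
                        f"{path}: line {lineno}: duplicate edge {a}-{b} with "
                        f"scores {seen[key]} and {score}"
                    )
                continue
            seen[key] = score
            if score < score_threshold:
                continue
            g.add_edge(a, b, weight=score / 1000.0)
    net = InteractionNetwork(organism_id=organism_id, graph=g)
    net.validate()
    return net


def write_string_edgelist(net: InteractionNetwork, path) -> None:
    """Write a network back to the STRING dialect (scores re-expanded to /1000)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for u, v, w in sorted(net.graph.edges(data="weight")):
            fh.write(f"{u} {v} {round(w * 1000)}\n")


def read_labels(path, organism_id: str | None = None) -> EssentialityLabels:
    """Read a two-column TSV of ``gene_id<TAB>essential|non-essential``.

    A ``gene_id`` / ``label`` header row is tolerated. A gene listed twice with
    the same label is collapsed silently; with conflicting labels it raises.
    """
    path = str(path)
    if organism_id is None:
        organism_id = path.rsplit("/", 1)[-1].split(".")[0]
    labels: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.rstrip("\n").split("\t")
            if len(tokens) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            gene, label = tokens[0].strip(), tokens[1].strip().lower()
            if lineno == 1 and (gene, label) == ("gene_id", "label"):
                continue
            if label not in _VALID_LABELS:
                raise ParseError(
                    f"{path}: line {lineno}: unknown label {tokens[1]!r} "
                    f"(expected {ESSENTIAL!r} or {NON_ESSENTIAL!r})"
                )
            is_ess = label == ESSENTIAL
            if gene in labels and labels[gene] != is_ess:
                raise ConsistencyError(f"{path}: line {lineno}: conflicting labels for {gene}")
            labels[gene] = is_ess
    return EssentialityLabels(organism_id=organism_id, labels=labels)


def write_labels(labels: EssentialityLabels, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlabel\n")
        for gene in sorted(labels.labels):
            fh.write(f"{gene}\t{ESSENTIAL if labels.labels[gene] else NON_ESSENTIAL}\n")


def restrict_to_network(labels: EssentialityLabels, net: InteractionNetwork) -> EssentialityLabels:
    """Keep only labels for genes present in the network.

    Returns a new :class:`EssentialityLabels`; the retained count and fraction
    are logged. Zero overlap yields an empty result with a ``UserWarning``
    rather than an exception, so a cohort loop can continue past a bad mapping.
    """
    if labels.organism_id != net.organism_id:
        raise ValueError(
            f"organism mismatch: labels {labels.organism_id!r} vs network {net.organism_id!r}"
        )
    present = {g: e for g, e in labels.labels.items() if g in net.graph}
    n_in, n_all = len(present), len(labels.labels)
    frac = n_in / n_all if n_all else 0.0
    logger.info("%s: %d/%d labelled genes in network (%.1f%%)", net.organism_id, n_in, n_all, 100 * frac)
    if n_all and n_in == 0:
        warnings.warn(
            f"{net.organism_id}: no labelled gene appears in the network", stacklevel=2
        )
    return EssentialityLabels(organism_id=labels.organism_id, labels=present)
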