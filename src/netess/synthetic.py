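"""Synthetic multi-organism cohorts with a planted centrality–lethality signal.

Each organism is a preferential-attachment (Barabási–Albert) graph — the
simplest generator with the heavy-tailed degree distribution characteristic of
protein-association networks — with association weights drawn uniformly from a
stated sub-interval of (0, 1]. Essentiality is planted through a logistic
coupling on the *standardised* degree,

    P(essential | v) = sigmoid(alpha_o + beta * z(v)),

where z(v) is the within-organism z-score of degree and alpha_o is solved
per organism so the expected essential fraction equals the target pi. Coupling
on standardised rather than raw degree is what makes the signal transfer
across organisms of very different size — the property the per-network
min-max scaling of real features is designed to exploit. Optional symmetric
label noise flips a stated fraction of labels after the coupling, and an
optional fragmentation step removes a fraction of edges to create
multi-component graphs for exercising component-sensitive measures.

Defaults model a small bacterial cohort: 6 organisms of 300–800 genes,
15% essential, coupling slope 2, 10% label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .network_io import InteractionNetwork, EssentialityLabels

DEFAULT_SIZE_RANGE = (300, 800)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``sizes`` may be given explicitly (one node count per organism) or drawn
    uniformly from ``size_range``. ``m`` is the preferential-attachment edges
    per new node; ``pi`` the target essential fraction; ``beta`` the coupling
    slope of essentiality log-odds on standardised degree; ``noise`` the
    fraction of labels flipped after coupling; ``weight_bounds`` the support of
    the uniform association-weight distribution; ``fragment`` an optional
    fraction of edges deleted post-generation.
    """

    n_organisms: int = 6
    sizes: list | None = None
    size_range: tuple = DEFAULT_SIZE_RANGE
    m: int = 3
    pi: float = 0.15
    beta: float = 2.0
    noise: float = 0.1
    weight_bounds: tuple = (0.15, 1.0)
    fragment: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sizes is not None:
            self.sizes = list(self.sizes)
            self.n_organisms = len(self.sizes)
            if any(n < self.m + 1 for n in self.sizes):
                raise ValueError(f"every organism needs > m={self.m} nodes")
        if not 0.0 < self.pi <= 0.5:
            raise ValueError("pi must lie in (0, 0.5]")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        lo, hi = self.weight_bounds
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("weight_bounds must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.fragment < 1.0:
            raise ValueError("fragment must lie in [0, 1)")


def _solve_intercept(z: np.ndarray, beta: float, pi: float) -> float:
    """alpha with mean(sigmoid(alpha + beta z)) == pi."""

    def gap(a):
        return expit(a + beta * z).mean() - pi

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"essential fraction pi={pi} unreachable with beta={beta}")
    return brentq(gap, lo, hi, xtol=1e-10)


def _generate_organism(org_id: str, n: int, spec: CohortSpec, rng: np.random.Generator):
    graph_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(n, spec.m, seed=graph_seed)
    mapping = {i: f"{org_id}_g{i:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    lo, hi = spec.weight_bounds
    # integer /1000 weights so the STRING dialect round-trips exactly
    lo_i, hi_i = max(1, round(lo * 1000)), round(hi * 1000)
    for u, v in g.edges:
        g.edges[u, v]["weight"] = int(rng.integers(lo_i, hi_i + 1)) / 1000.0
    if spec.fragment > 0:
        edges = sorted(g.edges)
        n_drop = int(round(spec.fragment * len(edges)))
        drop_idx = rng.choice(len(edges), size=n_drop, replace=False)
        g.remove_edges_from(edges[i] for i in drop_idx)
    nodes = sorted(g.nodes)
    deg = np.array([g.degree[v] for v in nodes], dtype=float)
    sd = deg.std()
    z = (deg - deg.mean()) / sd if sd > 0 else np.zeros_like(deg)
    alpha = _solve_intercept(z, spec.beta, spec.pi)
    essential = rng.random(n) < expit(alpha + spec.beta * z)
    if spec.noise > 0:
        n_flip = int(round(spec.noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        essential[flip] = ~essential[flip]
    net = InteractionNetwork(organism_id=org_id, graph=g)
    labels = EssentialityLabels(
        organism_id=org_id, labels={v: bool(e) for v, e in zip(nodes, essential)}
    )
    return net, labels


def generate_cohort(spec: CohortSpec) -> tuple[list, list]:
    """Generate the cohort: parallel lists of networks and labels.

    Fully determined by ``spec.seed``; the same spec always yields the same
    cohort, and each organism draws from an independent child stream.
    """
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.n_organisms)
    size_rng = np.random.default_rng(ss.spawn(1)[0])
    if spec.sizes is not None:
        sizes = spec.sizes
    else:
        lo, hi = spec.size_range
        sizes = [int(size_rng.integers(lo, hi + 1)) for _ in range(spec.n_organisms)]
    nets, labels = [], []
    for i, (n, c) in enumerate(zip(sizes, child)):
        net, lab = _generate_organism(f"org{i + 1:02d}", n, spec, np.random.default_rng(c))
        nets.append(net)
        labels.append(lab)
    return nets, labels


def generate_external_table(
    labels, n_informative: int, n_noise: int, effect: float, seed: int = 0
) -> pd.DataFrame:
    """Per-gene external feature table: informative columns are standard normal
    shifted by ``effect`` (in SD units) for essential genes; noise columns are
    pure standard normal. One row per labelled gene, indexed by gene_id.

    ``labels`` may be one EssentialityLabels or a sequence of them (rows
    concatenated; gene ids are assumed globally unique, as the cohort
    generator guarantees).
    """
    if n_informative + n_noise < 1:
        raise ValueError("need at least one column")
    if hasattr(labels, "labels"):
        labels = [labels]
    genes, y = [], []
    for lab in labels:
        for g in sorted(lab.labels):
            genes.append(g)
            y.append(lab.labels[g])
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    data = {}
    for i in range(n_informative):
        data[f"seq_inf_{i + 1:02d}"] = rng.standard_normal(len(genes)) + effect * y
    for i in range(n_noise):
        data[f"seq_noise_{i + 1:02d}"] = rng.standard_normal(len(genes))
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return df
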