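import networkx as nx
import numpy as np
import pytest

from netess import InteractionNetwork, EssentialityLabels


def as_network(g: nx.Graph, organism_id: str = "org", weight: float = 0.5) -> InteractionNetwork:
    """Wrap a bare networkx graph, filling in missing edge weights."""
    g = g.copy()
    for u, v, data in g.edges(data=True):
        data.setdefault("weight", weight)
    return InteractionNetwork(organism_id=organism_id, graph=g)


def random_network(rng: np.random.Generator, n_max: int = 7, organism_id: str = "rand") -> InteractionNetwork:
    """A small random graph with random edge probability and random weights."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.2, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in g.edges:
        g.edges[u, v]["weight"] = round(float(rng.uniform(0.1, 1.0)), 3)
    return InteractionNetwork(organism_id=organism_id, graph=g)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def triangle():
    return as_network(nx.complete_graph(3), "k3")


@pytest.fixture
def path4():
    return as_network(nx.path_graph(4), "p4", weight=1.0)


@pytest.fixture
def star5():
    # center 0 with 4 leaves
    return as_network(nx.star_graph(4), "star")


@pytest.fixture
def tiny_cohort():
    """Two 60/80-node organisms with a strong planted degree coupling."""
    from netess.synthetic import CohortSpec, generate_cohort

    nets, labels = generate_cohort(CohortSpec(sizes=[60, 80], beta=2.0, noise=0.0, seed=7))
    return nets, labels


def make_labels(mapping: dict, organism_id: str = "org") -> EssentialityLabels:
    return EssentialityLabels(organism_id=organism_id, labels=dict(mapping))
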