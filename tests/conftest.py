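"""Shared fixtures and independent oracles for the test suite."""

import random

import networkx as nx
import pytest

from dgmod import Partition, load_fixture
from dgmod.metrics import modularity


@pytest.fixture(scope="session")
def karate():
    """Zachary karate club graph with its two-faction reference partition."""
    return load_fixture("karate")


@pytest.fixture()
def joined_triangles():
    """Two triangles {0,1,2} and {3,4,5} joined by the bridge edge 2-3."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
    return g


@pytest.fixture()
def k3():
    return nx.complete_graph(3)


def set_partitions(items):
    """Yield every partition of ``items`` into non-empty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_max_modularity(g: nx.Graph) -> float:
    """Exhaustive maximum modularity over all set partitions (n <= ~10)."""
    best = -1.0
    for part in set_partitions(sorted(g.nodes)):
        q = modularity(g, Partition.from_communities(part))
        if q > best:
            best = q
    return best


def random_connected_graph(rng: random.Random, n_min=4, n_max=8) -> nx.Graph:
    """A small random connected simple graph with at least one edge."""
    while True:
        n = rng.randint(n_min, n_max)
        g = nx.gnp_random_graph(n, 0.5, seed=rng.randint(0, 2**31 - 1))
        if g.number_of_edges() >= 1 and nx.is_connected(g):
            return g
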