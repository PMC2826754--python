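import itertools
import random

import networkx as nx
import pytest

from netflow import ProbNetwork, QuerySet


@pytest.fixture
def chain_net():
    """Source-intermediate-sink chain, both edges 0.6."""
    return ProbNetwork.from_edges([("s", "m", 0.6), ("m", "t", 0.6)])


@pytest.fixture
def diamond_net():
    """Two node-disjoint 2-hop paths s-a-t and s-b-t, all edges 0.5."""
    return ProbNetwork.from_edges(
        [("s", "a", 0.5), ("a", "t", 0.5), ("s", "b", 0.5), ("b", "t", 0.5)]
    )


@pytest.fixture
def hub_contrast_net():
    """Sink u behind a degree-2 intermediate, sink v behind a hub.

    Both sinks hang off the query by one 2-edge path of identical
    reliabilities; v's intermediate has 8 extra edges.
    """
    edges = [("q", "a", 0.6), ("a", "u", 0.6), ("q", "b", 0.6), ("b", "v", 0.6)]
    edges += [("b", f"x{i}", 0.6) for i in range(8)]
    return ProbNetwork.from_edges(edges)


def make_random_net(rng: random.Random, max_nodes: int = 8, max_edges: int = 14,
                    weight_range=(0.1, 0.9)):
    """Small random connected-ish network for oracle comparisons."""
    n = rng.randint(4, max_nodes)
    nodes = [f"v{i}" for i in range(n)]
    pairs = list(itertools.combinations(nodes, 2))
    rng.shuffle(pairs)
    m = rng.randint(n - 1, min(max_edges, len(pairs)))
    edges = [(u, v, rng.uniform(*weight_range)) for u, v in pairs[:m]]
    return ProbNetwork.from_edges(edges)


def random_query_sink(rng: random.Random, net: ProbNetwork):
    nodes = sorted(net.nodes)
    k = rng.randint(1, min(2, len(nodes) - 1))
    members = rng.sample(nodes, k)
    sink = rng.choice([v for v in nodes if v not in members])
    return QuerySet(members), sink


def all_simple_paths_edge_disjoint(net: ProbNetwork, q: QuerySet, sink: str) -> bool:
    """True iff every pair of simple source->sink paths shares no edge."""
    g = net.graph
    paths = []
    for s in q:
        if s in g and sink in g:
            paths.extend(nx.all_simple_paths(g, s, sink))
    edge_sets = [
        {frozenset(e) for e in zip(p, p[1:])} for p in paths
    ]
    return all(
        not (a & b) for a, b in itertools.combinations(edge_sets, 2)
    )
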