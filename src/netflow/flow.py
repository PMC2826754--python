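"""Reliability lower bounds from maximum sets of edge-disjoint paths.

The two-terminal reliability between a query (source set) and a sink is
the probability that at least one fully operational path connects them
when each edge fails independently.  Computing it exactly is #P-hard, but
a set of *edge-disjoint* paths fails independently, so with ``d`` such
paths whose individual failure probabilities are ``P_i``::

    R  >=  1 - prod_{i=1..d} P_i,        P_i = 1 - prod_j r_j

is a provable lower bound, and it tightens as ``d`` grows.  By Menger's
theorem the maximum ``d`` equals the minimum cardinality source/sink edge
cut, obtained here as a unit-capacity maximum flow.  Multiple sources are
handled with a virtual super-source joined to each query member by an
artificial certain (r = 1) edge that never appears in reported paths.

Flow decompositions are not unique; paths are peeled greedily by maximum
reliability product (shortest path on ``-log r`` restricted to
flow-carrying arcs), which maximises the resulting bound among
decompositions of that flow, with lexicographic tie-breaking so output is
deterministic.

:func:`exact_reliability` enumerates all ``2^|E|`` edge states and is the
brute-force oracle the bound is verified against on small graphs.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms.flow import shortest_augmenting_path

from .network import ProbNetwork, QuerySet, validate_query

__all__ = [
    "DisjointPathSet",
    "ReliabilityResult",
    "max_edge_disjoint_paths",
    "max_flow_path_decomposition",
    "path_failure_probability",
    "reliability_lower_bound",
    "netflow_score",
    "rank_candidates",
    "exact_reliability",
]

# reserved super-source label; \x00 sorts before any printable id
_SUPER = "\x00__super_source__"


@dataclass(frozen=True)
class DisjointPathSet:
    """A certificate: pairwise edge-disjoint source->sink paths.

    ``paths[i]`` is a node sequence starting at a query member and ending
    at the sink; ``failures[i]`` is its failure probability
    ``P_i = 1 - prod r_j`` over its edges.
    """

    paths: tuple[tuple[str, ...], ...]
    failures: tuple[float, ...]

    @property
    def d(self) -> int:
        return len(self.paths)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(p) - 1 for p in self.paths)


@dataclass(frozen=True)
class ReliabilityResult:
    """Answer unit for one candidate: the bound plus its evidence."""

    sink: str
    bound: float
    d: int
    path_set: DisjointPathSet = field(repr=False)


def path_failure_probability(path: list[str] | tuple[str, ...], net) -> float:
    """Failure probability ``1 - prod r_j`` of a single path.

    ``net`` may be a :class:`ProbNetwork` or a bare ``networkx.Graph``
    with an ``"r"`` edge attribute.
    """
    g = net.graph if isinstance(net, ProbNetwork) else net
    prod = 1.0
    for u, v in zip(path, path[1:]):
        if not g.has_edge(u, v):
            raise ValueError(f"path step ({u!r}, {v!r}) is not a network edge")
        prod *= g[u][v]["r"]
    return 1.0 - prod


def reliability_lower_bound(pset: DisjointPathSet) -> float:
    """Eq.-style product bound ``1 - prod P_i``; 0 for an empty path set."""
    if pset.d == 0:
        return 0.0
    prod = 1.0
    for p in pset.failures:
        prod *= p
    return 1.0 - prod


def _flow_digraph(
    g: nx.Graph, sources: frozenset, sink: str, capacity: str | None = None
) -> nx.DiGraph:
    """Directed unit- or capacitated-flow network with a super-source.

    Each undirected edge becomes two opposing arcs of capacity 1 (or the
    ``capacity`` edge attribute); super-source arcs carry the total
    capacity incident to each query member, so one member can head
    several disjoint paths.
    """
    d = nx.DiGraph()
    for u, v in sorted((min(a, b), max(a, b)) for a, b in g.edges):
        cap = 1 if capacity is None else int(g[u][v][capacity])
        d.add_edge(u, v, capacity=cap)
        d.add_edge(v, u, capacity=cap)
    for s in sorted(sources):
        if s in g:
            cap = (
                g.degree[s]
                if capacity is None
                else sum(int(g[s][n][capacity]) for n in g[s])
            )
            d.add_edge(_SUPER, s, capacity=cap)
    return d


def _mincost_maxflow(
    g: nx.Graph, d: nx.DiGraph, sink: str
) -> tuple[int, dict[str, dict[str, int]]]:
    """Min-cost maximum flow by successive shortest paths with potentials.

    Arc cost is ``-log r`` (0 on super-source arcs), so among all maximum
    flows the returned one maximises the product of edge reliabilities
    it uses.  Dijkstra on reduced costs; deterministic tie-breaking by
    node id.
    """
    cap: dict[str, dict[str, int]] = {u: {} for u in d}
    cost: dict[str, dict[str, float]] = {u: {} for u in d}
    for u, v in d.edges:
        cap[u][v] = d[u][v]["capacity"]
        cap[v].setdefault(u, 0)  # residual reverse arc
        c = 0.0 if u == _SUPER else -math.log(g[u][v]["r"])
        cost[u][v] = c
        cost[v].setdefault(u, -c)
    pot = {u: 0.0 for u in d}
    flow: dict[str, dict[str, int]] = {u: {} for u in d}
    value = 0
    while True:
        dist = {_SUPER: 0.0}
        pred: dict[str, str] = {}
        heap: list[tuple[float, str]] = [(0.0, _SUPER)]
        done: set[str] = set()
        while heap:
            du, u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            if u == sink:
                break
            for v in sorted(cap[u]):
                if cap[u][v] <= 0 or v in done:
                    continue
                rc = cost[u][v] + pot[u] - pot[v]
                if rc < 0.0:  # float noise only; true reduced costs are >= 0
                    rc = 0.0
                alt = du + rc
                if alt < dist.get(v, math.inf) - 1e-15:
                    dist[v] = alt
                    pred[v] = u
                    heapq.heappush(heap, (alt, v))
        if sink not in done:
            return value, flow
        for u in done:
            pot[u] += dist[u]
        path = [sink]
        while path[-1] != _SUPER:
            path.append(pred[path[-1]])
        path.reverse()
        bottleneck = min(cap[u][v] for u, v in zip(path, path[1:]))
        for u, v in zip(path, path[1:]):
            cap[u][v] -= bottleneck
            cap[v][u] = cap[v].get(u, 0) + bottleneck
            flow[u][v] = flow[u].get(v, 0) + bottleneck
            back = flow[v].get(u, 0)
            if back:  # net out opposing flow
                c = min(back, flow[u][v])
                flow[v][u] -= c
                flow[u][v] -= c
        value += bottleneck


def _most_reliable_flow_path(
    flow: dict, g: nx.Graph, sink: str
) -> tuple[str, ...] | None:
    """Uniform-cost search on -log r over flow-carrying arcs.

    Deterministic: among minimum-cost paths the lexicographically
    smallest node sequence wins (heap orders by (cost, path)).
    """
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (_SUPER,))]
    done = set()
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node == sink:
            return path
        if node in done:
            continue
        done.add(node)
        for nbr, f in sorted(flow.get(node, {}).items()):
            if f <= 0 or nbr in done:
                continue
            w = 0.0 if node == _SUPER else -math.log(g[node][nbr]["r"])
            heapq.heappush(heap, (cost + w, path + (nbr,)))
    return None


def max_flow_path_decomposition(
    g: nx.Graph,
    sources: frozenset,
    sink: str,
    capacity: str | None = None,
    reliability_routed: bool = False,
) -> list[tuple[tuple[str, ...], int]]:
    """Maximum flow from a source set to ``sink``, decomposed into paths.

    With ``capacity=None`` every undirected edge has capacity 1 and the
    result is a maximum set of edge-disjoint paths each carrying one
    unit.  With a capacity attribute named, paths may carry several
    units (their bottleneck flow).  ``reliability_routed`` routes the
    maximum flow at minimum cost with arc cost ``-log r``, so among all
    maximum flows the one with the highest total reliability product is
    decomposed.  Paths are peeled greedily by maximum reliability
    product; each entry is ``(node_sequence, flow_units)``.
    """
    if sink in sources:
        raise ValueError(f"sink {sink!r} is a query member")
    if sink not in g:
        raise ValueError(f"sink {sink!r} not in network")
    if not any(s in g for s in sources) or g.degree[sink] == 0:
        return []

    d = _flow_digraph(g, sources, sink, capacity)
    if _SUPER not in d:
        return []
    if reliability_routed:
        value, flow = _mincost_maxflow(g, d, sink)
    else:
        value, flow = nx.maximum_flow(
            d, _SUPER, sink, flow_func=shortest_augmenting_path
        )
    value = int(round(value))
    if value == 0:
        return []

    # cancel opposing flow so each undirected edge is used in <= 1 direction
    flow = {u: dict(nbrs) for u, nbrs in flow.items()}
    for u, v in g.edges:
        f_uv = flow.get(u, {}).get(v, 0)
        f_vu = flow.get(v, {}).get(u, 0)
        cancel = min(f_uv, f_vu)
        if cancel:
            flow[u][v] -= cancel
            flow[v][u] -= cancel

    paths: list[tuple[tuple[str, ...], int]] = []
    remaining = value
    while remaining > 0:
        p = _most_reliable_flow_path(flow, g, sink)
        if p is None:  # flow conservation guarantees this never triggers
            raise RuntimeError("flow decomposition failed")
        units = min(flow[u][v] for u, v in zip(p, p[1:]))
        for u, v in zip(p, p[1:]):
            flow[u][v] -= units
        paths.append((p[1:], units))  # strip super-source
        remaining -= units
    return paths


def max_edge_disjoint_paths(net, sources, sink: str) -> DisjointPathSet:
    """Maximum set of pairwise edge-disjoint paths from ``sources`` to ``sink``.

    By Menger's theorem ``|paths|`` equals the minimum cardinality edge
    cut separating the source set from the sink.  A sink disconnected
    from every source yields an empty path set, not an error.
    """
    g = net.graph if isinstance(net, ProbNetwork) else net
    srcs = frozenset(sources.members if isinstance(sources, QuerySet) else sources)
    decomposition = max_flow_path_decomposition(g, srcs, sink, reliability_routed=True)
    paths = tuple(p for p, _ in decomposition)
    failures = tuple(path_failure_probability(p, g) for p in paths)
    return DisjointPathSet(paths, failures)


def netflow_score(net, q: QuerySet, sink: str) -> ReliabilityResult:
    """Lower bound on the reliability between query ``q`` and ``sink``.

    Composes the max edge-disjoint path computation with the product
    bound; the result never exceeds the exact two-terminal reliability.
    """
    pset = max_edge_disjoint_paths(net, q, sink)
    return ReliabilityResult(
        sink=sink,
        bound=reliability_lower_bound(pset),
        d=pset.d,
        path_set=pset,
    )


def rank_candidates(net: ProbNetwork, q: QuerySet) -> list[ReliabilityResult]:
    """Score every non-query node as the sink in turn.

    Returns results sorted by bound descending, ties broken by
    lexicographic node id so output is deterministic.
    """
    validate_query(net, q)
    results = [netflow_score(net, q, n) for n in sorted(net.nodes) if n not in q]
    results.sort(key=lambda r: (-r.bound, r.sink))
    return results


def exact_reliability(net, q, sink: str, max_edges: int = 20) -> float:
    """Exact source-set/sink reliability by edge-state enumeration.

    Sums the probability of every edge subset under which some query
    member is connected to the sink.  Exponential in ``|E|`` — refuse
    above ``max_edges`` (use Monte Carlo estimation instead).
    """
    g = net.graph if isinstance(net, ProbNetwork) else net
    srcs = frozenset(q.members if isinstance(q, QuerySet) else q)
    if sink in srcs:
        raise ValueError(f"sink {sink!r} is a query member")
    edges = sorted((min(a, b), max(a, b)) for a, b in g.edges)
    m = len(edges)
    if m > max_edges:
        raise ValueError(
            f"{m} edges exceeds enumeration cap {max_edges}; "
            "use mcs_reliability for an estimate"
        )
    probs = [g[u][v]["r"] for u, v in edges]
    nodes = {n: i for i, n in enumerate(sorted(g.nodes))}
    src_idx = [nodes[s] for s in srcs if s in nodes]
    sink_idx = nodes[sink]

    total = 0.0
    for mask in range(1 << m):
        parent = list(range(len(nodes)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        p = 1.0
        for j in range(m):
            if mask >> j & 1:
                p *= probs[j]
                a, b = edges[j]
                ra, rb = find(nodes[a]), find(nodes[b])
                if ra != rb:
                    parent[ra] = rb
            else:
                p *= 1.0 - probs[j]
        if any(find(s) == find(sink_idx) for s in src_idx):
            total += p
    return total
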