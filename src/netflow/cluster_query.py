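"""Cluster-graph bounds and hierarchical threshold/budget queries.

Scoring every protein in a proteome-scale network means one max-flow
instance per candidate.  The cluster machinery prunes most of them: the
network is summarised as a *cluster graph* whose vertices are clusters
(plus the query proteins as individual vertices) and whose edges carry
the **maximum** probability and the **count** (multiplicity) of original
edges crossing between the two member sets.  A path in the cluster graph
stands for up to ``bandwidth_i`` real edge-disjoint paths, where
``bandwidth_i`` is the multiplicity of the path's first edge out of the
query; the per-cluster optimistic bound is therefore::

    max_bound = 1 - prod_i  P_i ** bandwidth_i

with ``P_i`` the cluster-path failure probability.  Best-first search
expands the highest-bound cluster above the threshold into its children,
prunes clusters whose bound falls below it, and finally verifies each
surviving candidate with a true flow computation on the full network.
The number of full flow instances executed is the efficiency ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .clustering import Cluster, ClusterHierarchy
from .flow import (
    ReliabilityResult,
    max_flow_path_decomposition,
    netflow_score,
    path_failure_probability,
)
from .network import ProbNetwork, QuerySet, validate_query

__all__ = [
    "ClusterGraph",
    "ClusterBound",
    "QueryReport",
    "build_cluster_graph",
    "cluster_max_bound",
    "threshold_query",
    "adapt_threshold",
    "budgeted_query",
    "THRESHOLD_FLOOR",
]

THRESHOLD_FLOOR = 1e-6


@dataclass
class ClusterGraph:
    """Summary graph over an active cluster set plus query vertices.

    ``vertices`` maps each vertex id to its member node set (a query
    vertex maps to itself); ``edges`` maps a sorted vertex pair to
    ``(weight, multiplicity)`` where weight is the maximum crossing-edge
    probability and multiplicity the crossing-edge count.
    """

    vertices: dict[str, frozenset]
    edges: dict[tuple[str, str], tuple[float, int]]
    query: frozenset

    def multiplicity(self, a: str, b: str) -> int:
        return self.edges[(a, b) if a < b else (b, a)][1]

    def to_flow_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (a, b), (w, m) in self.edges.items():
            g.add_edge(a, b, r=w, mult=m)
        return g


@dataclass(frozen=True)
class ClusterBound:
    """Optimistic (bandwidth-modified) bound for one cluster vertex."""

    cluster: str
    max_bound: float
    paths: tuple[tuple[str, ...], ...] = ()
    bandwidths: tuple[int, ...] = ()


@dataclass
class QueryReport:
    """Query answer set plus the work ledger of the search."""

    answers: list[ReliabilityResult]
    threshold: float | None
    flow_instances_executed: int
    clusters_expanded: int
    clusters_pruned: int


def _clusters_as_pairs(clusters) -> list[tuple[str, frozenset]]:
    out = []
    for c in clusters:
        if isinstance(c, Cluster):
            out.append((c.id, c.members))
        else:
            cid, members = c
            out.append((str(cid), frozenset(members)))
    return out


def build_cluster_graph(net: ProbNetwork, clusters, q: QuerySet) -> ClusterGraph:
    """Cluster graph over an active cluster set, query proteins as vertices.

    Query members are stripped from their home clusters first; the
    remaining active member sets must disjointly cover all non-query
    nodes.  An edge joins two vertices iff at least one network edge
    crosses their member sets, carrying the max weight and the count.
    """
    validate_query(net, q)
    qset = frozenset(q.members)
    vertices: dict[str, frozenset] = {m: frozenset((m,)) for m in qset}
    node2vertex: dict[str, str] = {m: m for m in qset}
    for cid, members in _clusters_as_pairs(clusters):
        members = members - qset
        if not members:
            continue
        overlap = members & node2vertex.keys()
        if overlap:
            raise ValueError(
                f"overlapping active clusters at nodes {sorted(overlap)[:5]}"
            )
        vertices[cid] = members
        for v in members:
            node2vertex[v] = cid
    uncovered = net.nodes - node2vertex.keys()
    if uncovered:
        raise ValueError(
            f"active clusters do not cover nodes {sorted(uncovered)[:5]}"
        )
    edges: dict[tuple[str, str], tuple[float, int]] = {}
    for u, v, r in net.edges():
        a, b = node2vertex[u], node2vertex[v]
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        w, m = edges.get(key, (0.0, 0))
        edges[key] = (max(w, r), m + 1)
    return ClusterGraph(vertices=vertices, edges=edges, query=qset)


def cluster_max_bound(cg: ClusterGraph, q: QuerySet, target: str) -> ClusterBound:
    """Bandwidth-modified upper estimate of any target member's bound.

    Runs the flow computation on the cluster graph (query vertices as
    sources, edge capacities equal to multiplicities, so every real
    edge-disjoint path maps to a feasible unit of cluster flow) and
    peels it into paths.  A cluster path stands for as many real
    disjoint paths as the flow it carries — its *bandwidth*, which can
    never exceed the multiplicity of its first edge out of the query —
    so each path's failure probability enters the product bound raised
    to that bandwidth::

        max_bound = 1 - prod_i P_i ** bandwidth_i
    """
    if target not in cg.vertices:
        raise ValueError(f"target {target!r} is not a cluster-graph vertex")
    g = cg.to_flow_graph()
    decomposition = max_flow_path_decomposition(
        g, frozenset(q.members), target, capacity="mult", reliability_routed=True
    )
    if not decomposition:
        return ClusterBound(cluster=target, max_bound=0.0)
    paths = tuple(p for p, _ in decomposition)
    bandwidths = tuple(units for _, units in decomposition)
    prod = 1.0
    for p, bw in zip(paths, bandwidths):
        prod *= path_failure_probability(p, g) ** bw
    return ClusterBound(
        cluster=target, max_bound=1.0 - prod, paths=paths, bandwidths=bandwidths
    )


def adapt_threshold(
    threshold: float,
    policy: str,
    n_answers: int = 0,
    target_k: int | None = None,
    floor: float = THRESHOLD_FLOOR,
) -> float:
    """Next threshold under an adaptation policy.

    ``none`` keeps the threshold; ``halve`` halves it while the answer
    set is empty; ``target_k`` halves it until at least ``target_k``
    answers exist.  The floor stops runaway adaptation.
    """
    if policy == "none":
        return threshold
    if policy == "halve":
        return threshold * 0.5 if n_answers == 0 and threshold > floor else threshold
    if policy == "target_k":
        if target_k is None:
            raise ValueError("target_k policy needs target_k")
        return threshold * 0.5 if n_answers < target_k and threshold > floor else threshold
    raise ValueError(f"unknown adaptation policy {policy!r}")


class _SearchState:
    """Incrementally maintained cluster graph over the active cluster set.

    Expansion replaces one cluster vertex by its children and recomputes
    only the edges incident to the expanded cluster's members.
    """

    def __init__(self, net: ProbNetwork, h: ClusterHierarchy, q: QuerySet):
        validate_query(net, q)
        self.net = net
        self.h = h
        self.qset = frozenset(q.members)
        self.vertices: dict[str, frozenset] = {
            m: frozenset((m,)) for m in self.qset
        }
        self.node2vertex: dict[str, str] = {m: m for m in self.qset}
        self.active: set[str] = set()
        for rid in h.roots:
            members = h[rid].members - self.qset
            if members:
                self.vertices[rid] = members
                self.active.add(rid)
                for v in members:
                    self.node2vertex[v] = rid
        g = net.graph
        self.edges: dict[tuple[str, str], tuple[float, int]] = {}
        for u, v in g.edges:
            self._add_edge(u, v, g[u][v]["r"])

    def _add_edge(self, u: str, v: str, r: float) -> None:
        a = self.node2vertex.get(u)
        b = self.node2vertex.get(v)
        if a is None or b is None or a == b:  # accepted-leaf members drop out
            return
        key = (a, b) if a < b else (b, a)
        w, m = self.edges.get(key, (0.0, 0))
        self.edges[key] = (max(w, r), m + 1)

    def graph(self) -> ClusterGraph:
        return ClusterGraph(vertices=self.vertices, edges=self.edges, query=self.qset)

    def expand(self, cid: str) -> list[str]:
        """Replace ``cid`` by its children; returns the new active vertices."""
        cluster = self.h[cid]
        members = self.vertices.pop(cid)
        self.active.discard(cid)
        self.edges = {k: v for k, v in self.edges.items() if cid not in k}
        new_ids = []
        for kid in cluster.children:
            kms = self.h[kid].members - self.qset
            if not kms:
                continue
            self.vertices[kid] = kms
            self.active.add(kid)
            new_ids.append(kid)
            for v in kms:
                self.node2vertex[v] = kid
        g = self.net.graph
        for u in sorted(members):
            for v in g[u]:
                if v in members and v < u:
                    continue  # intra-set edge counted once
                self._add_edge(u, v, g[u][v]["r"])
        return new_ids


def _run_search(
    state: _SearchState,
    q: QuerySet,
    threshold: float,
    bounds: dict[str, float],
    strict: bool,
    delivered: list[tuple[float, str]],
    candidate_of: dict[str, tuple[float, str]],
) -> tuple[int, int]:
    """Best-first expansion at a fixed threshold.

    Returns (n_expanded, n_pruned_now).  ``bounds`` caches cluster
    bounds across calls (and across adaptive threshold drops);
    ``strict`` recomputes every active bound after each graph change.
    ``delivered`` records accepted leaves as (bound, cluster id);
    ``candidate_of`` maps candidate node -> its delivering leaf record.
    """
    expanded = 0
    while True:
        cg = state.graph()
        todo = sorted(state.active if strict else state.active - bounds.keys())
        for cid in todo:
            bounds[cid] = cluster_max_bound(cg, q, cid).max_bound
        frontier = [
            (bounds[c], c) for c in state.active if bounds[c] >= threshold
        ]
        if not frontier:
            pruned = sum(1 for c in state.active if bounds[c] < threshold)
            return expanded, pruned
        frontier.sort(key=lambda t: (-t[0], t[1]))
        bound, best = frontier[0]
        if state.h[best].is_leaf:
            # accepted leaf: members become candidates for individual
            # verification; the leaf stays a summary-graph vertex so other
            # clusters' bounds keep its connectivity
            for m in sorted(state.vertices[best]):
                candidate_of[m] = (bound, best)
            delivered.append((bound, best))
            state.active.discard(best)
        else:
            state.expand(best)
            bounds.pop(best, None)
            expanded += 1


def threshold_query(
    net: ProbNetwork,
    h: ClusterHierarchy,
    q: QuerySet,
    threshold: float,
    adapt: str = "none",
    target_k: int | None = None,
    strict: bool = False,
) -> QueryReport:
    """All candidates whose reliability bound meets the threshold.

    Best-first hierarchical search: starting from the hierarchy roots,
    the highest-bound cluster above the threshold is expanded; clusters
    whose optimistic bound stays below it are pruned with all their
    members.  Members of accepted leaves are then verified with a true
    flow computation on the full network, and only verified bounds >=
    the (possibly adapted) threshold are answered.

    ``adapt``: ``none`` | ``halve`` | ``target_k`` (see
    :func:`adapt_threshold`).  ``strict`` recomputes all cluster bounds
    after every expansion instead of reusing cached ones.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    state = _SearchState(net, h, q)
    bounds: dict[str, float] = {}
    delivered: list[tuple[float, str]] = []
    candidate_of: dict[str, tuple[float, str]] = {}
    verified: dict[str, ReliabilityResult] = {}
    expanded_total = 0
    thr = threshold
    while True:
        exp, pruned = _run_search(state, q, thr, bounds, strict, delivered, candidate_of)
        expanded_total += exp
        for node in sorted(candidate_of.keys() - verified.keys()):
            verified[node] = netflow_score(net, q, node)
        answers = [r for r in verified.values() if r.bound >= thr]
        new_thr = adapt_threshold(thr, adapt, len(answers), target_k)
        if new_thr == thr:
            break
        thr = new_thr
    answers.sort(key=lambda r: (-r.bound, r.sink))
    return QueryReport(
        answers=answers,
        threshold=thr,
        flow_instances_executed=len(verified),
        clusters_expanded=expanded_total,
        clusters_pruned=pruned,
    )


def budgeted_query(
    net: ProbNetwork,
    h: ClusterHierarchy,
    q: QuerySet,
    fraction: float,
) -> QueryReport:
    """Approximate query under a fixed budget of flow instances.

    Best-first expansion with no threshold orders every node by the
    optimistic bound of its delivering leaf cluster; only the top
    ``ceil(fraction * n_non_query)`` candidates get a true flow
    computation.  ``fraction=1.0`` reproduces exhaustive ranking.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    state = _SearchState(net, h, q)
    bounds: dict[str, float] = {}
    delivered: list[tuple[float, str]] = []
    candidate_of: dict[str, tuple[float, str]] = {}
    leaf_members = {
        c.id: sorted(c.members - state.qset) for c in h.clusters.values() if c.is_leaf
    }
    expanded, _ = _run_search(
        state, q, -math.inf, bounds, False, delivered, candidate_of
    )
    delivered.sort(key=lambda t: (-t[0], t[1]))
    candidates = [m for _, leaf in delivered for m in leaf_members[leaf]]
    n_total = len(net.nodes - state.qset)
    n_exec = min(len(candidates), math.ceil(fraction * n_total))
    answers = [netflow_score(net, q, node) for node in candidates[:n_exec]]
    answers.sort(key=lambda r: (-r.bound, r.sink))
    return QueryReport(
        answers=answers,
        threshold=None,
        flow_instances_executed=n_exec,
        clusters_expanded=expanded,
        clusters_pruned=0,
    )
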