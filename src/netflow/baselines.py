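"""Comparison methods: Monte Carlo reliability and random walk with restart.

MCS estimates two-terminal reliability by sampling edge operational
states (each edge kept independently with its probability) and testing
whether a kept path — optionally length-capped, the literature uses a
cutoff of 4 — connects the query to the sink.  It converges to the exact
reliability but offers no proven bound at finite sample size.

RWR represents the degree-normalising school: a walker follows
column-normalised edge weights and teleports back to the query with
fixed restart probability.  Because normalisation divides each node's
outgoing weights by their sum, affinity leaking through a high-degree
intermediate is diluted — the behaviour the flow bound deliberately
avoids.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .network import ProbNetwork, QuerySet, validate_query

__all__ = ["MCSEstimate", "RWRAffinity", "mcs_reliability", "random_walk_with_restart"]


@dataclass(frozen=True)
class MCSEstimate:
    sink: str
    estimate: float
    n_samples: int
    stderr: float
    max_path_len: int | None
    seed: int


@dataclass(frozen=True)
class RWRAffinity:
    """Stationary visiting distribution; affinities sum to 1."""

    affinities: dict[str, float] = field(repr=False)
    restart_prob: float = 0.5

    def __getitem__(self, node: str) -> float:
        return self.affinities[node]


def _connected(
    adj: list[list[tuple[int, int]]],
    kept: np.ndarray,
    sources: list[int],
    sink: int,
    max_len: int | None,
) -> bool:
    """BFS from the query side over kept edges, early exit at the sink.

    With ``max_len`` set, only sink visits within that many hops count.
    """
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        du = dist[u]
        if max_len is not None and du >= max_len:
            continue
        for v, ei in adj[u]:
            if kept[ei] and v not in dist:
                if v == sink:
                    return True
                dist[v] = du + 1
                queue.append(v)
    return False


def mcs_reliability(
    net: ProbNetwork,
    q: QuerySet,
    sink: str,
    n_samples: int = 10000,
    max_path_len: int | None = None,
    seed: int = 0,
) -> MCSEstimate:
    """Monte Carlo estimate of query->sink reliability.

    Each sample keeps every edge independently with its reliability and
    scores 1 iff a kept path of length <= ``max_path_len`` (unbounded
    when ``None``, the default) connects some query member to the sink.
    Deterministic given ``seed``.
    """
    validate_query(net, q)
    if sink in q:
        raise ValueError(f"sink {sink!r} is a query member")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    nodes = sorted(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = list(net.edges())
    probs = np.array([r for _, _, r in edges])
    adj: list[list[tuple[int, int]]] = [[] for _ in nodes]
    for ei, (u, v, _) in enumerate(edges):
        adj[idx[u]].append((idx[v], ei))
        adj[idx[v]].append((idx[u], ei))
    sources = [idx[m] for m in q.members]
    sink_i = idx[sink]

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 4096
    remaining = n_samples
    while remaining:
        n = min(chunk, remaining)
        kept_block = rng.random((n, len(edges))) < probs
        for row in kept_block:
            if _connected(adj, row, sources, sink_i, max_path_len):
                hits += 1
        remaining -= n
    est = hits / n_samples
    stderr = float(np.sqrt(est * (1.0 - est) / n_samples))
    return MCSEstimate(
        sink=sink,
        estimate=est,
        n_samples=n_samples,
        stderr=stderr,
        max_path_len=max_path_len,
        seed=seed,
    )


def random_walk_with_restart(
    net: ProbNetwork,
    q: QuerySet,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> RWRAffinity:
    """Stationary affinities of a restarting random walk from the query.

    Transition matrix W column-normalises edge weights (each node's
    outgoing weights divided by their sum); the affinity vector solves
    ``x = (1 - c) W x + c e`` with ``e`` uniform over the query members
    and ``c`` the restart probability, by power iteration to L1 change
    below ``tol``.
    """
    validate_query(net, q)
    if not (0.0 < restart_prob < 1.0):
        raise ValueError("restart_prob must be in (0, 1)")
    nodes = sorted(net.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    wsum = np.zeros(n)
    for u, v, r in net.edges():
        wsum[idx[u]] += r
        wsum[idx[v]] += r
    dead = [m for m in sorted(q.members) if wsum[idx[m]] == 0.0]
    if dead:
        raise ValueError(f"query members with zero weighted degree: {dead}")

    rows, cols, vals = [], [], []
    for u, v, r in net.edges():
        iu, iv = idx[u], idx[v]
        rows.append(iu); cols.append(iv); vals.append(r / wsum[iv])
        rows.append(iv); cols.append(iu); vals.append(r / wsum[iu])
    from scipy.sparse import csr_matrix

    w = csr_matrix((vals, (rows, cols)), shape=(n, n))

    e = np.zeros(n)
    for m in q.members:
        e[idx[m]] = 1.0 / len(q)
    c = restart_prob
    x = e.copy()
    for _ in range(max_iter):
        x_new = (1.0 - c) * (w @ x) + c * e
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return RWRAffinity(
        affinities={v: float(x[idx[v]]) for v in nodes}, restart_prob=restart_prob
    )
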