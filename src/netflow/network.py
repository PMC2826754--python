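"""Data model and file I/O for probabilistic protein interaction networks.

A probabilistic interaction network is an undirected simple graph whose
nodes are proteins (opaque, case-sensitive string identifiers) and whose
edges carry a reliability ``r`` in ``(0, 1]`` — the probability that the
interaction is functional.  All downstream reliability computations treat
edge failures as independent Bernoulli events.

Two plain-text formats are supported:

* **tsv** — one edge per line: ``node_a<TAB>node_b<TAB>probability``
  (any whitespace accepted as separator, ``#`` starts a comment line).
* **sif** — ``node_a pp node_b probability`` with an interaction-type
  token between the endpoints.

Duplicate rows for the same unordered pair are collapsed keeping the
maximum probability; conflicting evidence for a pair is thereby resolved
optimistically, matching how cluster-graph edges summarise crossing edges.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "NetworkFormatError",
    "ProbNetwork",
    "QuerySet",
    "load_network",
    "write_network",
    "load_query",
    "validate_query",
]


class NetworkFormatError(ValueError):
    """Raised for malformed network/query files or invalid edge data."""


@dataclass(frozen=True)
class QuerySet:
    """The partially known complex/pathway: a nonempty set of node ids."""

    members: frozenset

    def __init__(self, members: Iterable[str]):
        object.__setattr__(self, "members", frozenset(members))
        if not self.members:
            raise NetworkFormatError("query set must be nonempty")

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def __contains__(self, node: str) -> bool:
        return node in self.members

    def __len__(self) -> int:
        return len(self.members)


class ProbNetwork:
    """Undirected simple graph with per-edge interaction probability.

    Thin validated wrapper around :class:`networkx.Graph`; the reliability
    of edge ``(u, v)`` is stored in the ``"r"`` edge attribute.
    """

    def __init__(self, graph: nx.Graph):
        self._g = graph
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "ProbNetwork":
        """Build a network from ``(u, v, r)`` triples.

        Duplicate unordered pairs are collapsed keeping the maximum r.
        """
        g = nx.Graph()
        for u, v, r in edges:
            u, v = str(u), str(v)
            r = float(r)
            if u == v:
                raise NetworkFormatError(f"self-loop on node {u!r} rejected")
            if not (0.0 < r <= 1.0):
                raise NetworkFormatError(
                    f"edge ({u!r}, {v!r}) reliability {r} outside (0, 1]"
                )
            if g.has_edge(u, v):
                if r > g[u][v]["r"]:
                    g[u][v]["r"] = r
            else:
                g.add_edge(u, v, r=r)
        if g.number_of_nodes() == 0:
            raise NetworkFormatError("empty network")
        return cls(g)

    def _validate(self) -> None:
        if self._g.number_of_nodes() == 0:
            raise NetworkFormatError("empty network")
        for u, v, data in self._g.edges(data=True):
            if u == v:
                raise NetworkFormatError(f"self-loop on node {u!r}")
            r = data.get("r")
            if r is None or not (0.0 < float(r) <= 1.0):
                raise NetworkFormatError(
                    f"edge ({u!r}, {v!r}) reliability {r} outside (0, 1]"
                )

    # -- accessors ----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield edges as ``(u, v, r)`` in deterministic sorted order."""
        for u, v in sorted((min(a, b), max(a, b)) for a, b in self._g.edges):
            yield u, v, self._g[u][v]["r"]

    def reliability(self, u: str, v: str) -> float:
        if not self._g.has_edge(u, v):
            raise NetworkFormatError(f"no edge between {u!r} and {v!r}")
        return self._g[u][v]["r"]

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {(u, v): r for u, v, r in self.edges()}
        theirs = {(u, v): r for u, v, r in other.edges()}
        if mine.keys() != theirs.keys():
            return False
        return all(abs(mine[k] - theirs[k]) < 1e-9 for k in mine)

    def __repr__(self) -> str:
        return (
            f"ProbNetwork({self._g.number_of_nodes()} nodes, "
            f"{self._g.number_of_edges()} edges)"
        )


# -- file I/O ---------------------------------------------------------


def _parse_row(fields: list[str], fmt: str, lineno: int) -> tuple[str, str, float]:
    if fmt == "tsv":
        if len(fields) != 3:
            raise NetworkFormatError(
                f"line {lineno}: expected 'node_a node_b probability', got {fields!r}"
            )
        u, v, rs = fields
    else:  # sif: node_a pp node_b probability
        if len(fields) != 4:
            raise NetworkFormatError(
                f"line {lineno}: expected 'node_a <type> node_b probability', "
                f"got {fields!r}"
            )
        u, _, v, rs = fields
    try:
        r = float(rs)
    except ValueError as exc:
        raise NetworkFormatError(
            f"line {lineno}: probability {rs!r} is not a number"
        ) from exc
    return u, v, r


def load_network(path: str | os.PathLike, format: str = "tsv") -> ProbNetwork:
    """Load a probabilistic network from an edge-list file.

    Duplicate rows for one unordered pair keep the maximum probability.
    Rows with r outside (0, 1] raise :class:`NetworkFormatError` naming
    the offending line.
    """
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown format {format!r}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, r = _parse_row(line.split(), format, lineno)
            if u == v:
                raise NetworkFormatError(f"line {lineno}: self-loop on {u!r}")
            if not (0.0 < r <= 1.0):
                raise NetworkFormatError(
                    f"line {lineno}: probability {r} outside (0, 1]"
                )
            if g.has_edge(u, v):
                if r > g[u][v]["r"]:
                    g[u][v]["r"] = r
            else:
                g.add_edge(u, v, r=r)
    if g.number_of_nodes() == 0:
        raise NetworkFormatError(f"{path}: empty network")
    return ProbNetwork(g)


def write_network(net: ProbNetwork, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a network to disk; round-trips through :func:`load_network`."""
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown format {format!r}")
    if net.number_of_nodes() == 0:
        raise NetworkFormatError("refusing to write an empty network")
    with open(path, "w") as fh:
        for u, v, r in net.edges():
            if format == "tsv":
                fh.write(f"{u}\t{v}\t{r:.9g}\n")
            else:
                fh.write(f"{u}\tpp\t{v}\t{r:.9g}\n")


def load_query(path: str | os.PathLike) -> QuerySet:
    """Load a query set: one node id per line, '#' comments ignored."""
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line)
    if not members:
        raise NetworkFormatError(f"{path}: empty query")
    return QuerySet(members)


def validate_query(net: ProbNetwork, q: QuerySet) -> QuerySet:
    """Check every query member is a node of ``net``; return ``q`` unchanged."""
    missing = sorted(m for m in q.members if m not in net)
    if missing:
        raise NetworkFormatError(
            f"query members not in network: {', '.join(missing)}"
        )
    return q
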