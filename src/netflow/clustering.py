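"""Flat and hierarchical clusterings of a probabilistic network.

Two flat schemes are provided.  *Spectral clustering* treats the
interaction-probability matrix M as a similarity matrix, takes the
eigenvectors of the k largest eigenvalues and k-means-clusters their
rows.  *Nearest Neighbor Clustering* (NNC) greedily absorbs edges in
decreasing weight order under a hard cluster-size cap, which keeps
cluster sizes near-uniform and pushes high-weight edges inside clusters —
exactly what the cluster-graph max-weight summary wants minimised between
clusters.

A hierarchy is built by running NNC on the leaf level and then,
recursively, on the max-weight cluster graph of each level, with the size
cap counted in protein members.  Hierarchies are what the threshold-query
search prunes.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkFormatError, ProbNetwork

__all__ = [
    "Cluster",
    "ClusterHierarchy",
    "spectral_cluster",
    "nnc_cluster",
    "build_hierarchy",
    "save_hierarchy",
    "load_hierarchy",
    "DEFAULT_LEAF_SIZE",
    "DEFAULT_LEVEL_SIZES",
]

# Sized for proteome-scale networks (thousands of nodes): leaf clusters of
# up to 100 strongly-interacting proteins, grouped 4x per level above.
DEFAULT_LEAF_SIZE = 100
DEFAULT_LEVEL_SIZES: tuple[float, ...] = (100, 400, 1600, math.inf)


@dataclass(frozen=True)
class Cluster:
    """A (possibly nested) group of proteins.

    ``level`` 0 marks leaves; a non-leaf's members are the disjoint union
    of its children's members.
    """

    id: str
    members: frozenset
    level: int = 0
    children: tuple[str, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterHierarchy:
    """Nested partition of the node set; leaves partition the network."""

    clusters: dict[str, Cluster] = field(default_factory=dict)
    roots: list[str] = field(default_factory=list)

    def __getitem__(self, cid: str) -> Cluster:
        return self.clusters[cid]

    def leaves(self) -> list[Cluster]:
        return sorted(
            (c for c in self.clusters.values() if c.is_leaf), key=lambda c: c.id
        )

    def validate(self) -> None:
        seen: set = set()
        for c in self.clusters.values():
            if c.children:
                kids = [self.clusters[k] for k in c.children]
                union = frozenset().union(*(k.members for k in kids))
                if union != c.members:
                    raise ValueError(f"cluster {c.id}: members != union of children")
                if sum(len(k.members) for k in kids) != len(c.members):
                    raise ValueError(f"cluster {c.id}: overlapping children")
                if any(k.level >= c.level for k in kids):
                    raise ValueError(f"cluster {c.id}: child level not below parent")
            else:
                if seen & c.members:
                    raise ValueError(f"leaf {c.id} overlaps another leaf")
                seen |= c.members
        root_union = frozenset().union(
            *(self.clusters[r].members for r in self.roots)
        ) if self.roots else frozenset()
        if root_union != seen:
            raise ValueError("roots do not cover all leaves")


# -- flat clusterings -------------------------------------------------


def spectral_cluster(net: ProbNetwork, k: int, seed: int) -> list[Cluster]:
    """k-way spectral clustering of the similarity matrix M(i,j) = r(i,j).

    Eigen-decomposes M as-is (no Laplacian normalisation), embeds each
    node as its row in the top-k eigenvector matrix, then runs k-means
    (k-means++ init, 10 restarts) with the given seed.  Returns <= k
    nonempty clusters; deterministic given the seed.
    """
    from sklearn.cluster import KMeans

    nodes = sorted(net.nodes)
    n = len(nodes)
    if not (2 <= k <= n):
        raise ValueError(f"k={k} out of range [2, {n}]")
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, r in net.edges():
        m[idx[u], idx[v]] = r
        m[idx[v], idx[u]] = r
    vals, vecs = np.linalg.eigh(m)
    embed = vecs[:, np.argsort(vals)[::-1][:k]]
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(embed)
    groups: dict[int, list[str]] = {}
    for v, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(v)
    member_sets = sorted((frozenset(g) for g in groups.values()), key=min)
    return [
        Cluster(id=f"s{i}", members=ms, level=0)
        for i, ms in enumerate(member_sets)
    ]


def _nnc_partition(
    items: list[str],
    sizes: dict[str, int],
    edges: list[tuple[float, str, str]],
    max_size: float,
) -> list[frozenset]:
    """Greedy NNC over weighted items; size of a group is the sum of item sizes.

    Edges are absorbed in decreasing weight order (ties by lexicographic
    endpoints): new pair -> new group, one assigned -> insert, both
    assigned -> merge; any action that would exceed ``max_size`` is
    skipped.  Unassigned items end as singletons.
    """
    assign: dict[str, int] = {}
    groups: dict[int, set[str]] = {}
    gsize: dict[int, int] = {}
    nxt = 0
    for w, u, v in sorted(edges, key=lambda e: (-e[0], e[1], e[2])):
        gu, gv = assign.get(u), assign.get(v)
        if gu is None and gv is None:
            if sizes[u] + sizes[v] <= max_size:
                groups[nxt] = {u, v}
                gsize[nxt] = sizes[u] + sizes[v]
                assign[u] = assign[v] = nxt
                nxt += 1
        elif gu is None or gv is None:
            gid, newcomer = (gv, u) if gu is None else (gu, v)
            if gsize[gid] + sizes[newcomer] <= max_size:
                groups[gid].add(newcomer)
                gsize[gid] += sizes[newcomer]
                assign[newcomer] = gid
        elif gu != gv:
            if gsize[gu] + gsize[gv] <= max_size:
                for x in groups[gv]:
                    assign[x] = gu
                groups[gu] |= groups.pop(gv)
                gsize[gu] += gsize.pop(gv)
    parts = [frozenset(g) for g in groups.values()]
    parts.extend(frozenset((x,)) for x in items if x not in assign)
    return sorted(parts, key=min)


def nnc_cluster(net: ProbNetwork, max_size: int) -> list[Cluster]:
    """Nearest Neighbor Clustering of the network under a size cap.

    Processes edges in decreasing reliability order and grows/merges
    clusters, skipping any step whose result would exceed ``max_size``
    members; isolated leftovers become singleton clusters.
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    items = sorted(net.nodes)
    parts = _nnc_partition(
        items,
        {v: 1 for v in items},
        [(r, u, v) for u, v, r in net.edges()],
        max_size,
    )
    return [Cluster(id=f"c{i}", members=ms, level=0) for i, ms in enumerate(parts)]


# -- hierarchy --------------------------------------------------------


def build_hierarchy(
    net: ProbNetwork,
    leaf_size: int = DEFAULT_LEAF_SIZE,
    level_sizes: tuple[float, ...] = DEFAULT_LEVEL_SIZES,
) -> ClusterHierarchy:
    """Recursive NNC hierarchy.

    Leaves come from ``nnc_cluster(net, leaf_size)``; each higher level
    groups the level below by NNC on its max-weight cluster graph, with
    the level's size bound counted in protein members.  ``level_sizes``
    must start with ``leaf_size`` and strictly increase (``math.inf``
    allowed last).
    """
    sizes = tuple(level_sizes)
    if not sizes or sizes[0] != leaf_size:
        raise ValueError("level_sizes must start with leaf_size")
    if any(a >= b for a, b in zip(sizes, sizes[1:])):
        raise ValueError("level_sizes must be strictly increasing")

    h = ClusterHierarchy()
    current = nnc_cluster(net, leaf_size)
    for c in current:
        h.clusters[c.id] = c

    owner = {v: c.id for c in current for v in c.members}
    for level, cap in enumerate(sizes[1:], start=1):
        if len(current) == 1:
            break
        # max-weight inter-cluster edges of the level below
        best: dict[tuple[str, str], float] = {}
        for u, v, r in net.edges():
            cu, cv = owner[u], owner[v]
            if cu == cv:
                continue
            key = (cu, cv) if cu < cv else (cv, cu)
            if r > best.get(key, 0.0):
                best[key] = r
        ids = sorted(c.id for c in current)
        csizes = {c.id: len(c.members) for c in current}
        parts = _nnc_partition(
            ids, csizes, [(w, a, b) for (a, b), w in best.items()], cap
        )
        nxt = []
        for i, child_ids in enumerate(parts):
            kids = tuple(sorted(child_ids))
            members = frozenset().union(*(h.clusters[k].members for k in kids))
            c = Cluster(id=f"L{level}_{i}", members=members, level=level, children=kids)
            h.clusters[c.id] = c
            nxt.append(c)
        current = nxt
        owner = {v: c.id for c in current for v in c.members}
    h.roots = sorted(c.id for c in current)
    h.validate()
    return h


def hierarchy_from_flat(clusters: list[Cluster]) -> ClusterHierarchy:
    """Wrap a flat clustering as a one-level hierarchy (all clusters roots)."""
    h = ClusterHierarchy(clusters={c.id: c for c in clusters},
                         roots=sorted(c.id for c in clusters))
    h.validate()
    return h


# -- JSON serialisation ----------------------------------------------


def save_hierarchy(h: ClusterHierarchy, path: str | os.PathLike) -> None:
    payload = {
        "clusters": [
            {
                "id": c.id,
                "level": c.level,
                "members": sorted(c.members),
                "children": list(c.children),
            }
            for c in sorted(h.clusters.values(), key=lambda c: c.id)
        ],
        "roots": list(h.roots),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_hierarchy(path: str | os.PathLike) -> ClusterHierarchy:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        clusters = {
            rec["id"]: Cluster(
                id=rec["id"],
                members=frozenset(rec["members"]),
                level=int(rec["level"]),
                children=tuple(rec.get("children", ())),
            )
            for rec in payload["clusters"]
        }
        h = ClusterHierarchy(clusters=clusters, roots=list(payload["roots"]))
    except (KeyError, TypeError) as exc:
        raise NetworkFormatError(f"{path}: malformed hierarchy JSON") from exc
    h.validate()
    return h
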