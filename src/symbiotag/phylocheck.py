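"""Host-specificity check via UPGMA on pairwise identity distances.

A deliberately simple stand-in for likelihood tree building: the claim being
verified is that symbiont phylotypes form separable host-specific clusters,
not fine phylogenetic structure.  Distances are 1 - identity; UPGMA
(average linkage, weighted by cluster size) yields an ultrametric dendrogram
whose clades are tested for per-host monophyly.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import numpy as np

from .clustering import pairwise_identity


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or (self.d < 0).any():
            raise ValueError("distance matrix must be symmetric and non-negative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclasses.dataclass
class Node:
    """Dendrogram node; ``height`` is the merge distance / 2 (0 for leaves)."""

    height: float
    children: tuple["Node", ...] = ()
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


def distance_matrix(
    representatives: Mapping[str, str] | Iterable[tuple[str, str]],
    truncate: bool = True,
) -> DistanceMatrix:
    """Pairwise 1 - identity among representative sequences.

    With ``truncate`` (default) each pair is cut to the shorter length before
    alignment, consistent with the clustering stage's treatment of reads as
    5'-anchored prefixes.
    """
    pairs = (
        list(representatives.items())
        if isinstance(representatives, Mapping)
        else list(representatives)
    )
    labels = [p[0] for p in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    if len(labels) < 2:
        raise ValueError("need at least two representatives")
    seqs = [p[1] for p in pairs]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            if truncate:
                L = min(len(a), len(b))
                a, b = a[:L], b[:L]
            d[i, j] = d[j, i] = 1.0 - pairwise_identity(a, b)
    return DistanceMatrix(labels=labels, d=d)


def upgma(dm: DistanceMatrix) -> Node:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Repeatedly merges the closest pair of clusters at height d/2, updating
    distances as the size-weighted average.  Ties are broken by label order
    (each cluster keyed by its lexicographically smallest leaf), so an
    all-equal matrix yields a caterpillar in label order.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least two leaves")
    nodes = {i: Node(0.0, label=dm.labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    keys = {i: dm.labels[i] for i in range(n)}  # smallest leaf label per cluster
    dist = {(i, j): dm.d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            dist,
            key=lambda ij: (dist[ij], min(keys[ij[0]], keys[ij[1]]),
                            max(keys[ij[0]], keys[ij[1]])),
        )
        i, j = best
        d_merge = dist[best]
        left, right = sorted((i, j), key=lambda k: keys[k])
        node = Node(
            height=d_merge / 2.0, children=(nodes[left], nodes[right])
        )
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            dist[(k, new)] = (sizes[i] * d_ik + sizes[j] * d_jk) / (
                sizes[i] + sizes[j]
            )
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        active -= {i, j}
        active.add(new)
        nodes[new] = node
        sizes[new] = sizes[i] + sizes[j]
        keys[new] = min(keys[i], keys[j])
    return nodes[next_id - 1]


def to_newick(root: Node) -> str:
    """Newick string with branch lengths derived from node heights."""

    def fmt(node: Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{length:.6f}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{length:.6f}"

    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def is_ultrametric(root: Node, tol: float = 1e-9) -> bool:
    """Heights must be non-increasing from every node down to its children."""
    for node in root.walk():
        for c in node.children:
            if c.height > node.height + tol:
                return False
    return True


def host_monophyly(
    root: Node, host_map: Mapping[str, str]
) -> tuple[dict[str, bool], bool]:
    """Per-host monophyly: some clade's leaf set equals the host's phylotypes.

    A single-phylotype host is trivially monophyletic (a leaf is a clade).
    Raises if any leaf lacks a host assignment.
    """
    leaves = root.leaves()
    missing = [x for x in leaves if x not in host_map]
    if missing:
        raise ValueError(f"leaves without host assignment: {missing}")
    clades = {frozenset(node.leaves()) for node in root.walk()}
    by_host: dict[str, set[str]] = {}
    for leaf in leaves:
        by_host.setdefault(host_map[leaf], set()).add(leaf)
    result = {host: frozenset(members) in clades for host, members in by_host.items()}
    return result, all(result.values())
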