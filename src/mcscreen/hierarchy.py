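"""Agglomerative clustering with the squared-dissimilarity Ward convention
and a dynamic hybrid dendrogram cut.

The two building blocks used by both the expression screen and the
phylogenetic-profile clustering live here:

``ward_linkage``
    Ward agglomeration in the "ward.D2" convention: the Lance-Williams
    update is applied to *squared* dissimilarities and merge heights are
    reported back on the distance scale.  Ties between equal-criterion
    merges are broken lexicographically on the (smallest member, largest
    member) pair of original item indices, so the merge sequence is fully
    deterministic.

``dynamic_hybrid_cut``
    A dynamic hybrid tree cut: candidate clusters are detected on the
    dendrogram by recursively splitting branches whose children are
    separated by a sufficient height gap and are internally tight (both
    criteria modulated by ``deep_split``), then items left unlabeled are
    assigned to the nearest cluster medoid.  Items are labeled with
    positive integers; ``UNASSIGNED`` (0) is returned only when no branch
    qualifies as a cluster at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.spatial.distance import squareform

UNASSIGNED = 0

#: deep_split in 0..4 -> maximum normalized core scatter of a branch that
#: may still be declared a cluster; larger values split more aggressively.
_DEEP_SPLIT_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class ClusterAssignment:
    """Partition of items into clusters (0 = unassigned)."""

    items: list
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.items) != len(self.labels):
            raise ValueError("items and labels must have equal length")

    def as_dict(self) -> dict:
        return dict(zip(self.items, (int(x) for x in self.labels)))

    def members(self, cluster: int) -> list:
        return [it for it, lab in zip(self.items, self.labels) if lab == cluster]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in set(self.labels) if c != UNASSIGNED)

    def sizes(self) -> dict[int, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.cluster_ids}


def _as_square(dist: np.ndarray) -> np.ndarray:
    """Accept a square or condensed distance matrix; validate and square it up."""
    d = np.asarray(dist, dtype=float)
    if d.ndim == 1:
        d = squareform(d)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square or condensed")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def ward_linkage(dist: np.ndarray) -> np.ndarray:
    """Ward.D2 agglomeration of a dissimilarity matrix.

    Parameters
    ----------
    dist
        Square symmetric (or condensed) dissimilarity matrix, n >= 2.

    Returns
    -------
    Z : ndarray of shape (n - 1, 4)
        scipy-style linkage rows ``(node_a, node_b, height, size)`` where
        original items are nodes ``0..n-1`` and the cluster created by
        merge ``k`` is node ``n + k``.  Heights are on the input distance
        scale (square root of the Ward criterion applied to squared
        dissimilarities).
    """
    D = _as_square(dist)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two items")

    S = D.astype(float) ** 2  # working matrix of squared Ward distances
    np.fill_diagonal(S, np.inf)
    size = np.ones(n)
    rep = np.arange(n)  # smallest original index in each active cluster
    node = np.arange(n)  # dendrogram node id of each active cluster
    alive = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        m = S.min()
        tol = 1e-9 * max(m, 1.0) + 1e-12
        cand = np.argwhere(S <= m + tol)
        best = None
        best_key = None
        for i, j in cand:
            if i >= j:
                continue
            key = (min(rep[i], rep[j]), max(rep[i], rep[j]))
            if best_key is None or key < best_key:
                best_key = key
                best = (int(i), int(j))
        i, j = best  # type: ignore[misc]
        height = float(np.sqrt(max(S[i, j], 0.0)))

        si, sj = size[i], size[j]
        others = alive.copy()
        others[i] = others[j] = False
        sk = size[others]
        merged = ((si + sk) * S[i, others] + (sj + sk) * S[j, others]
                  - sk * S[i, j]) / (si + sj + sk)
        S[i, others] = merged
        S[others, i] = merged
        S[i, i] = np.inf
        S[j, :] = np.inf
        S[:, j] = np.inf
        alive[j] = False

        Z[step] = (min(node[i], node[j]), max(node[i], node[j]),
                   height, si + sj)
        size[i] = si + sj
        rep[i] = min(rep[i], rep[j])
        node[i] = n + step

    return Z


class _Tree:
    """Per-node member lists, heights and core scatter of a linkage tree."""

    def __init__(self, Z: np.ndarray, n: int) -> None:
        self.n = n
        self.Z = Z
        n_nodes = 2 * n - 1
        self.height = np.zeros(n_nodes)
        self.children: list[tuple[int, int] | None] = [None] * n_nodes
        self.parent = np.full(n_nodes, -1, dtype=int)
        self.members: list[list[int]] = [[i] for i in range(n)] + [[] for _ in range(n - 1)]
        # sum and count of internal merge heights below each node
        self._hsum = np.zeros(n_nodes)
        self._hcnt = np.zeros(n_nodes, dtype=int)
        for k in range(n - 1):
            a, b = int(Z[k, 0]), int(Z[k, 1])
            node = n + k
            self.children[node] = (a, b)
            self.parent[a] = self.parent[b] = node
            self.height[node] = Z[k, 2]
            self.members[node] = self.members[a] + self.members[b]
            self._hsum[node] = self._hsum[a] + self._hsum[b] + Z[k, 2]
            self._hcnt[node] = self._hcnt[a] + self._hcnt[b] + 1

    def size(self, node: int) -> int:
        return len(self.members[node])

    def core_scatter(self, node: int, base: float) -> float:
        """Mean merge height inside the subtree (``base`` for singletons)."""
        if self._hcnt[node] == 0:
            return base
        return float(self._hsum[node] / self._hcnt[node])


def dynamic_hybrid_cut(
    Z: np.ndarray,
    dist: np.ndarray,
    deep_split: int = 2,
    min_cluster_size: int = 20,
    cut_height: float | None = None,
    items: Sequence[Any] | None = None,
) -> ClusterAssignment:
    """Cut a Ward dendrogram into clusters with the dynamic hybrid procedure.

    Stage 1 detects candidate clusters on the tree: the dendrogram is cut
    at ``cut_height`` (default 99% of the top merge height) and each
    resulting branch is recursively split whenever *both* children look
    like clusters -- at least ``min_cluster_size`` members, separated from
    the parent merge by a minimum normalized gap, and internally tighter
    than a maximum normalized core scatter.  Both limits follow from
    ``deep_split`` (0 = conservative .. 4 = aggressive).  Stage 2 assigns
    every remaining unlabeled item to the cluster with the nearest medoid.

    Returns a :class:`ClusterAssignment` with labels 1..K ordered by
    decreasing core size (ties by smallest member index); 0 means
    unassigned, which only happens when no branch qualifies.
    """
    if not (0 <= int(deep_split) <= 4):
        raise ValueError("deep_split must be an integer in 0..4")
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")
    D = _as_square(dist)
    n = D.shape[0]
    if Z.shape[0] != n - 1:
        raise ValueError("dendrogram and distance matrix disagree on item count")
    if items is None:
        items = list(range(n))
    items = list(items)
    if len(items) != n:
        raise ValueError("items must match the distance matrix order")

    heights = Z[:, 2]
    if cut_height is None:
        cut_height = 0.99 * float(heights.max())
    tree = _Tree(Z, n)

    base = float(np.quantile(heights, 0.05))
    hrange = cut_height - base
    max_core = _DEEP_SPLIT_CORE_SCATTER[int(deep_split)]
    min_gap = (1.0 - max_core) * 0.75

    # branch roots: maximal nodes at or below the cut
    roots = []
    for node in range(2 * n - 1):
        h = tree.height[node]
        if h > cut_height:
            continue
        par = tree.parent[node]
        if par == -1 or tree.height[par] > cut_height:
            roots.append(node)

    def cluster_like(child: int, parent_height: float) -> bool:
        if tree.size(child) < min_cluster_size:
            return False
        if hrange <= 0:
            return False
        gap = (parent_height - tree.height[child]) / hrange
        core = (tree.core_scatter(child, base) - base) / hrange
        return gap >= min_gap and core <= max_core

    terminal: list[int] = []

    def descend(node: int) -> None:
        kids = tree.children[node]
        if kids is None:
            terminal.append(node)
            return
        a, b = kids
        h = tree.height[node]
        # a merge is a genuine split point when at least one side hangs as
        # a tight, well-separated branch; composite siblings are descended
        # further instead of freezing the whole subtree
        if cluster_like(a, h) or cluster_like(b, h):
            descend(a)
            descend(b)
        else:
            terminal.append(node)

    for r in roots:
        descend(r)

    cores = [tree.members[t] for t in terminal if tree.size(t) >= min_cluster_size]
    cores.sort(key=lambda mem: (-len(mem), min(mem)))

    labels = np.zeros(n, dtype=int)
    for lab, mem in enumerate(cores, start=1):
        labels[mem] = lab

    if cores:
        # medoid-proximity assignment of stray items
        medoids = []
        for mem in cores:
            sub = D[np.ix_(mem, mem)]
            within = sub.sum(axis=1)
            medoids.append(mem[int(np.argmin(within))])
        stray = np.where(labels == UNASSIGNED)[0]
        for it in stray:
            dmed = D[it, medoids]
            labels[it] = int(np.argmin(dmed)) + 1

    return ClusterAssignment(
        items=items,
        labels=labels,
        params={
            "linkage": "ward.D2",
            "cut": "hybrid",
            "deep_split": int(deep_split),
            "min_cluster_size": int(min_cluster_size),
            "cut_height": float(cut_height),
        },
    )
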