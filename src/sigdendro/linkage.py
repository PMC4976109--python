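"""Complete-linkage agglomeration, normalized merge heights, and tree cuts.

Complete linkage defines the distance between two clusters as the maximum
pairwise Euclidean distance between their members, which guarantees that
merge heights are non-decreasing along the agglomeration.  Heights are made
scale-free by dividing by sqrt(n_v), the root of the profile dimension, so
that a height of 1 corresponds to an average per-variable separation of one
(standardized) unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from sigdendro.io import DataMatrix

__all__ = [
    "DendrogramModel",
    "MergeHeights",
    "agglomerate",
    "normalized_heights",
    "cut_at_height",
    "cut_k_clusters",
    "canonical_labels",
    "to_newick",
]


@dataclass
class DendrogramModel:
    """The agglomeration tree over sample columns.

    ``merges`` and ``heights`` follow the standard linkage-matrix layout:
    row i merges nodes ``merges[i, 0]`` and ``merges[i, 1]`` (leaves are
    0..n_leaves-1, internal nodes n_leaves+i) at distance ``heights[i]``.
    """

    merges: np.ndarray  # (n_leaves - 1, 2) integer child references
    heights: np.ndarray  # (n_leaves - 1,) merge distances, non-decreasing
    n_leaves: int
    linkage: str = "complete"
    metric: str = "euclidean"
    leaf_ids: list[str] | None = None
    n_v: int | None = None  # profile dimension used to build the tree

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 2):
            raise ValueError("merges must have shape (n_leaves - 1, 2)")
        if self.heights.shape != (self.n_leaves - 1,):
            raise ValueError("heights must have length n_leaves - 1")
        if np.any(self.heights < 0):
            raise ValueError("merge heights must be non-negative")
        if self.linkage == "complete" and np.any(np.diff(self.heights) < 0):
            raise ValueError("complete-linkage heights must be non-decreasing")

    def to_scipy(self) -> np.ndarray:
        """Standard (n-1) x 4 linkage matrix (children, height, cluster size)."""
        n = self.n_leaves
        Z = np.zeros((n - 1, 4))
        sizes = np.ones(2 * n - 1)
        for i, (a, b) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            Z[i] = (a, b, self.heights[i], sizes[n + i])
        return Z

    def scaled(self, factor: float) -> "DendrogramModel":
        """Same topology with all heights multiplied by ``factor``."""
        return DendrogramModel(
            merges=self.merges,
            heights=self.heights * factor,
            n_leaves=self.n_leaves,
            linkage=self.linkage,
            metric=self.metric,
            leaf_ids=self.leaf_ids,
            n_v=self.n_v,
        )


@dataclass
class MergeHeights:
    """Sorted vector of the n_s - 1 agglomeration heights, raw or normalized."""

    values: np.ndarray
    normalized: bool = False
    n_v_used: int | None = None

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


def agglomerate(Z: DataMatrix, linkage: str = "complete", metric: str = "euclidean") -> DendrogramModel:
    """Cluster the columns of Z agglomeratively.

    Only complete linkage with Euclidean distance is supported: this is the
    combination whose merge-height monotonicity and permutation-null behavior
    the detection procedure relies on.
    """
    if linkage != "complete":
        raise ValueError(f"only complete linkage is supported, got {linkage!r}")
    if metric != "euclidean":
        raise ValueError(f"only the euclidean metric is supported, got {metric!r}")
    if Z.n_s < 2:
        raise ValueError("need at least two sample columns to cluster")
    L = scipy_linkage(pdist(Z.values.T, metric="euclidean"), method="complete")
    return DendrogramModel(
        merges=L[:, :2].astype(int),
        heights=L[:, 2].copy(),
        n_leaves=Z.n_s,
        leaf_ids=list(Z.col_ids),
        n_v=Z.n_v,
    )


def normalized_heights(d: DendrogramModel, n_v: int) -> MergeHeights:
    """Merge heights divided by sqrt(n_v), sorted non-decreasing."""
    if n_v < 1:
        raise ValueError("n_v must be a positive count")
    if d.n_v is not None and n_v != d.n_v:
        raise ValueError(
            f"n_v={n_v} does not match the {d.n_v} variables used to build the tree"
        )
    return MergeHeights(d.heights / np.sqrt(n_v), normalized=True, n_v_used=n_v)


def canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by decreasing cluster size, ties by first appearance."""
    raw = np.asarray(raw).ravel()
    uniq, first, counts = np.unique(raw, return_index=True, return_counts=True)
    order = sorted(range(uniq.size), key=lambda i: (-counts[i], first[i]))
    remap = {uniq[i]: rank + 1 for rank, i in enumerate(order)}
    return np.array([remap[v] for v in raw], dtype=int)


def cut_at_height(d: DendrogramModel, h: float) -> np.ndarray:
    """Flat partition obtained by performing every merge with height <= h.

    The number of clusters equals 1 + #{merge heights > h}; labels are
    canonical (1..k by decreasing size).  ``h`` must be on the same scale as
    the tree's heights — normalize consistently before cutting.
    """
    raw = fcluster(d.to_scipy(), t=h, criterion="distance")
    return canonical_labels(raw)


def cut_k_clusters(d: DendrogramModel, k: int) -> np.ndarray:
    """Flat partition with exactly k clusters (undo the k - 1 last merges)."""
    if not (1 <= k <= d.n_leaves):
        raise ValueError(f"k must be in 1..{d.n_leaves}, got {k}")
    raw = cut_tree(d.to_scipy(), n_clusters=k).ravel()
    return canonical_labels(raw)


def to_newick(d: DendrogramModel) -> str:
    """Newick export of the dendrogram with ultrametric branch lengths.

    Each node is placed at half its merge height (so the height of a clade
    equals the complete-linkage distance at which it formed); leaves sit at
    depth 0.  Branch length = parent placement - child placement.
    """
    n = d.n_leaves
    ids = d.leaf_ids or [f"s{j + 1}" for j in range(n)]
    # placement[i]: distance of node i from the leaves, half the merge height
    placement = np.zeros(2 * n - 1)
    placement[n:] = d.heights / 2.0

    # iterative post-order build (recursion would overflow on large trees)
    rendered: dict[int, str] = {}
    root = 2 * n - 2
    stack = [root]
    while stack:
        node = stack[-1]
        if node < n:
            rendered[node] = ids[node]
            stack.pop()
            continue
        a, b = (int(x) for x in d.merges[node - n])
        if a in rendered and b in rendered:
            h = placement[node]
            parts = []
            for child in (a, b):
                parts.append(f"{rendered.pop(child)}:{h - placement[child]:.10g}")
            rendered[node] = "(" + ",".join(parts) + ")"
            stack.pop()
        else:
            stack.extend(c for c in (a, b) if c not in rendered)
    return rendered[root] + ";"
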