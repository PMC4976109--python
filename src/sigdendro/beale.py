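"""Beale's pseudo-F comparator for choosing a cluster count.

Beale's statistic tests whether partitioning the samples into k clusters
reduces the within-group sum of squares significantly more than chance,
relative to the single-cluster null.  With S1 the total sum of squares
about the grand mean profile and S2 the within-cluster sum of squares
under the k-group partition,

    F = ((S1 - S2) / S2) / ( ((n_s - 1)/(n_s - k)) * k^(2/n_v) - 1 )

is referred to an F distribution with n_v*(k - 1) and n_v*(n_s - k)
degrees of freedom.  The scan walks the nested cuts of a complete-linkage
dendrogram for k = 2..k_max and selects the k maximizing F if that maximum
is significant, else a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from sigdendro.io import DataMatrix
from sigdendro.linkage import DendrogramModel, cut_k_clusters

__all__ = ["BealeScanResult", "beale_f", "beale_select"]


@dataclass
class BealeScanResult:
    """Outcome of the nested-cut pseudo-F scan."""

    k_selected: int  # 1 when no scanned k reached significance
    k_scanned: np.ndarray  # the k values 2..k_max actually evaluated
    f_values: np.ndarray  # F statistic per scanned k
    p_values: np.ndarray  # upper-tail F probability per scanned k
    alpha: float
    k_max: int
    labels: np.ndarray | None = None  # partition at k_selected (None when k=1... see select)


def _values(Z) -> np.ndarray:
    return Z.values if isinstance(Z, DataMatrix) else np.asarray(Z, dtype=float)


def _f_from_ss(S1: float, S2: float, n_s: int, k: int, n_v: int):
    df1 = n_v * (k - 1)
    df2 = n_v * (n_s - k)
    if S2 <= 0.0:
        return np.inf, df1, df2, 0.0
    denom = ((n_s - 1) / (n_s - k)) * k ** (2.0 / n_v) - 1.0
    F = ((S1 - S2) / S2) / denom
    return F, df1, df2, float(f_dist.sf(F, df1, df2))


def beale_f(Z, labels_k, n_v: int | None = None):
    """Pseudo-F of a k-cluster partition against the single-cluster null.

    ``Z`` is a profile matrix (variables x samples, :class:`DataMatrix` or
    array); ``labels_k`` assigns each column to one of k >= 2 non-empty
    clusters.  Returns ``(F, df1, df2, p_value)``.  Perfectly tight
    clusters (S2 = 0) give F = +inf with p = 0.
    """
    V = _values(Z)
    labels = np.asarray(labels_k).ravel()
    n_vv, n_s = V.shape
    if n_v is None:
        n_v = n_vv
    elif n_v != n_vv:
        raise ValueError(f"n_v={n_v} does not match the matrix ({n_vv} rows)")
    if labels.size != n_s:
        raise ValueError("labels must assign every sample column")
    uniq, codes, counts = np.unique(labels, return_inverse=True, return_counts=True)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least two clusters to compare against one")
    if np.any(counts == 0):
        raise ValueError("empty cluster in labels")
    grand = V.mean(axis=1, keepdims=True)
    S1 = float(((V - grand) ** 2).sum())
    # within-cluster SS via per-cluster sums: sum(x^2) - |sum|^2 / m
    sums = np.zeros((n_v, k))
    np.add.at(sums.T, codes, V.T)
    sq = float((V**2).sum())
    S2 = sq - float((sums**2 / counts).sum())
    S2 = max(S2, 0.0)
    return _f_from_ss(S1, S2, n_s, k, n_v)


def _merge_stats(d: DendrogramModel, V: np.ndarray):
    """Per-merge reduction in within-cluster sum of squares, in merge order.

    Splitting internal node t into its children reduces the within SS by
    SS(t) - SS(left) - SS(right), computable from per-node counts, sum
    vectors and sums of squares accumulated bottom-up.
    """
    n_v, n = V.shape
    m = np.zeros(2 * n - 1)
    s = np.zeros((2 * n - 1, n_v))
    q = np.zeros(2 * n - 1)
    m[:n] = 1.0
    s[:n] = V.T
    q[:n] = (V**2).sum(axis=0)
    ss = np.zeros(2 * n - 1)  # within SS of each node's member set
    gain = np.zeros(n - 1)
    for i, (a, b) in enumerate(d.merges):
        t = n + i
        m[t] = m[a] + m[b]
        s[t] = s[a] + s[b]
        q[t] = q[a] + q[b]
        ss[t] = max(q[t] - (s[t] @ s[t]) / m[t], 0.0)
        gain[i] = ss[t] - ss[a] - ss[b]
    return ss[2 * n - 2], gain  # (S1 = total SS, per-merge gains)


def beale_select(
    d: DendrogramModel,
    Z,
    alpha: float = 0.05,
    k_max: int = 500,
    with_labels: bool = True,
) -> BealeScanResult:
    """Scan nested dendrogram cuts k = 2..k_max with the max-F rule.

    For each k, the k-cluster cut of the tree (undoing the k - 1 highest
    merges) is scored with Beale's pseudo-F against the single-cluster
    null.  If the maximum F over the scan is significant at ``alpha``, the
    corresponding k (ties toward smaller k) is selected; otherwise the data
    are declared a single cluster.  The within-cluster sums of squares are
    updated incrementally along the nested cuts, so the scan costs
    O(n_s * n_v) overall.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    V = _values(Z)
    n_v, n_s = V.shape
    if n_s != d.n_leaves:
        raise ValueError("dendrogram and matrix disagree on the number of samples")
    hi = min(k_max, n_s - 1)  # k = n_s has zero residual df
    S1, gain = _merge_stats(d, V)
    ks = np.arange(2, hi + 1)
    # the k-cluster cut removes the last k-1 merges: cumulative gains from the top
    removed = np.cumsum(gain[::-1])[: ks.size]
    S2 = np.maximum(S1 - removed, 0.0)
    f_values = np.empty(ks.size)
    p_values = np.empty(ks.size)
    for idx, k in enumerate(ks):
        F, _, _, p = _f_from_ss(S1, S2[idx], n_s, int(k), n_v)
        f_values[idx] = F
        p_values[idx] = p
    if ks.size == 0:
        return BealeScanResult(1, ks, f_values, p_values, alpha, k_max, None)
    best = int(np.argmax(f_values))  # argmax takes the first (smallest k) on ties
    if p_values[best] < alpha:
        k_selected = int(ks[best])
    else:
        k_selected = 1
    labels = None
    if with_labels:
        labels = cut_k_clusters(d, k_selected) if k_selected > 1 else np.ones(n_s, dtype=int)
    return BealeScanResult(
        k_selected=k_selected,
        k_scanned=ks,
        f_values=f_values,
        p_values=p_values,
        alpha=alpha,
        k_max=k_max,
        labels=labels,
    )
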