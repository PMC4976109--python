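"""Agreement metrics between a true and an inferred partition.

Three complementary measures:

* ``pwc`` — proportion of wrong clusters, (n_detected - n_true)/(D - n_true)
  with D the number of samples (or a cap for scan-based selectors): 0 when
  the cluster count is exact, 1 when every sample is its own cluster,
  negative when clusters were merged.
* ``cramers_v`` — chi-squared dependency of the true-by-inferred contingency
  table, (chi2/n)/min(r-1, c-1).  Equals 1 under perfect dependency even
  when true clusters are merged into larger ones, so it measures whether
  the agglomeration sorted the samples correctly regardless of the cut.
* ``jaccard_similarity`` — average Jaccard overlap over cluster pairs,
  divided by max(#true, #inferred); reaches 1 only when the partitions are
  identical, so it additionally penalizes wrong cluster counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

__all__ = [
    "ContingencyTable",
    "contingency",
    "pwc",
    "cramers_v",
    "jaccard_similarity",
]


@dataclass
class ContingencyTable:
    """Cross-classification counts of true (rows) vs inferred (columns) labels."""

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() != self.n:
            raise ValueError("counts must sum to n")
        if np.any(self.counts.sum(axis=1) == 0) or np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("table must have no all-zero row or column")

    @property
    def r(self) -> int:
        return self.counts.shape[0]

    @property
    def c(self) -> int:
        return self.counts.shape[1]


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels).ravel()
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency(true_labels, inferred_labels) -> ContingencyTable:
    """Count objects in each (true cluster, inferred cluster) cell."""
    t = _as_codes(true_labels)
    i = _as_codes(inferred_labels)
    if t.size != i.size:
        raise ValueError(
            f"label vectors differ in length: {t.size} vs {i.size}"
        )
    if t.size == 0:
        raise ValueError("label vectors must be non-empty")
    counts = np.zeros((t.max() + 1, i.max() + 1), dtype=int)
    np.add.at(counts, (t, i), 1)
    return ContingencyTable(counts=counts, n=t.size)


def pwc(
    n_detected: int, n_true: int, n_samples: int, denominator_cap: int | None = None
) -> float:
    """Proportion of wrong clusters, (n_detected - n_true) / (D - n_true).

    D defaults to the sample count n_samples (there are at most n_samples
    clusters, of which n_samples - n_true are wrong); pass
    ``denominator_cap`` when the selector scans a bounded number of
    partitions (e.g. 500 for the Beale scan) so the error is expressed as a
    proportion of the scan range instead.
    """
    D = n_samples if denominator_cap is None else denominator_cap
    if not (1 <= n_true <= n_samples):
        raise ValueError(f"n_true must be in 1..{n_samples}, got {n_true}")
    if not (1 <= n_detected <= max(n_samples, D)):
        raise ValueError(f"n_detected out of range: {n_detected}")
    if D == n_true:
        raise ValueError("degenerate denominator: cap equals the true cluster count")
    return (n_detected - n_true) / (D - n_true)


def cramers_v(tab: ContingencyTable, classic: bool = False) -> float:
    """Dependency index (chi2/n)/min(r-1, c-1) on the contingency table.

    This is the square of the textbook Cramer's V; pass ``classic=True``
    for the square-root variant.  Undefined (raises) when either partition
    has a single cluster.
    """
    if tab.r < 2 or tab.c < 2:
        raise ValueError(
            "index undefined: both partitions need at least two clusters "
            f"(got {tab.r} x {tab.c})"
        )
    chi2 = chi2_contingency(tab.counts, correction=False).statistic
    v2 = (chi2 / tab.n) / min(tab.r - 1, tab.c - 1)
    v2 = min(float(v2), 1.0)  # guard tiny float excess at perfect dependency
    return float(np.sqrt(v2)) if classic else v2


def jaccard_similarity(true_labels, inferred_labels) -> float:
    """Average Jaccard overlap, sum_ij |Ti ∩ Ij| / |Ti ∪ Ij|, over max(r, c)."""
    tab = contingency(true_labels, inferred_labels)
    p = tab.counts.astype(float)
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    q = row + col - p  # |union| per (true, inferred) pair
    return float((p / q).sum() / max(tab.r, tab.c))
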