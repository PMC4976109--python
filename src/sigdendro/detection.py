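"""End-to-end significant-cluster detection.

The six-step procedure: standardize rows; agglomerate the observed columns
and record the normalized heights D_o; build the row-permutation reference
D_e from r replicates; pick the p-th percentile of D_e as threshold; cut
the observed dendrogram there.  Clades that merged above the threshold are
kept apart, so the partition contains 1 + #{D_o > threshold} clusters, and
the expected proportion of false clusters under the no-cluster null is
alpha = 1 - p/100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from sigdendro.io import DataMatrix, standardize_rows
from sigdendro.linkage import (
    DendrogramModel,
    MergeHeights,
    agglomerate,
    cut_at_height,
    normalized_heights,
)
from sigdendro.null_reference import (
    ReferenceDistribution,
    percentile,
    reference_heights,
)

__all__ = ["DetectionResult", "alpha_from_percentile", "detect_clusters", "detect_scan"]

logger = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Partition of the sample columns with its significance provenance."""

    labels: np.ndarray  # 1..n_clusters, numbered by decreasing size
    n_clusters: int
    threshold: float  # cut height on the normalized scale
    percentile_p: float
    alpha: float
    r: int
    seed: int | None
    col_ids: list[str]
    heights: MergeHeights | None = None  # observed normalized D_o
    reference: ReferenceDistribution | None = None  # D_e
    dendrogram: DendrogramModel | None = None  # observed tree, normalized scale


def alpha_from_percentile(p: float) -> float:
    """Significance level alpha = 1 - p/100 for a cut at the p-th percentile."""
    if not (0.0 < p <= 100.0):
        raise ValueError(f"percentile p must be in (0, 100], got {p}")
    return 1.0 - p / 100.0


def detect_scan(
    X: DataMatrix,
    percentiles,
    r: int = 10,
    seed: int | None = None,
    standardize: str = "mean_sd",
    trim_fraction: float = 0.05,
) -> dict[float, DetectionResult]:
    """Run detection at several percentiles reusing one reference D_e.

    The reference distribution does not depend on the percentile, so a scan
    over cut levels (as when choosing a threshold from the QQ-plot) costs a
    single set of permutation replicates.  Returns ``{p: DetectionResult}``.
    """
    percentiles = [float(p) for p in percentiles]
    for p in percentiles:
        alpha_from_percentile(p)  # validates range

    Z = X if X.standardized else standardize_rows(X, method=standardize, trim_fraction=trim_fraction)
    d_raw = agglomerate(Z)
    D_o = normalized_heights(d_raw, Z.n_v)
    d_norm = d_raw.scaled(1.0 / np.sqrt(Z.n_v))
    ref = reference_heights(Z, r=r, seed=seed)

    out: dict[float, DetectionResult] = {}
    for p in percentiles:
        thr = percentile(ref, p)
        labels = cut_at_height(d_norm, thr)
        n_clusters = int(labels.max())
        if n_clusters == 1:
            logger.warning(
                "no significant structure at alpha=%.4g (threshold %.4g >= max height)",
                alpha_from_percentile(p),
                thr,
            )
        out[p] = DetectionResult(
            labels=labels,
            n_clusters=n_clusters,
            threshold=thr,
            percentile_p=p,
            alpha=alpha_from_percentile(p),
            r=r,
            seed=seed,
            col_ids=list(Z.col_ids),
            heights=D_o,
            reference=ref,
            dendrogram=d_norm,
        )
    return out


def detect_clusters(
    X: DataMatrix,
    p: float = 95.0,
    r: int = 10,
    seed: int | None = None,
    standardize: str = "mean_sd",
    trim_fraction: float = 0.05,
) -> DetectionResult:
    """Detect significant clusters by cutting at the p-th percentile of D_e.

    Parameters
    ----------
    X
        Profile matrix (variables x samples).  Standardized in place of the
        analysis if not already flagged as standardized.
    p
        Percentile of the reference distribution used as cut height; the
        significance level of the resulting clusters is 1 - p/100.
    r
        Number of row-permutation replicates for the reference (10 is
        typically sufficient).
    seed
        Seed for the permutation stream; required for reproducibility.
    """
    return detect_scan(
        X, [p], r=r, seed=seed, standardize=standardize, trim_fraction=trim_fraction
    )[float(p)]
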