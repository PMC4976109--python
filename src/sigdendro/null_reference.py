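"""Row-permutation reference distribution of dendrogram merge heights.

Independently reshuffling the entries of each variable (row) of the
standardized matrix destroys any grouping of the sample columns while
preserving every row's marginal distribution exactly.  Repeating the
agglomeration on r such reshuffles and averaging the sorted, normalized
height vectors element-wise yields the reference distribution D_e: the
expected heights of the branch points when the data hold no clusters.
Extreme percentiles of D_e are the cut heights at which observed clades
become "significant".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigdendro.io import DataMatrix
from sigdendro.linkage import MergeHeights, agglomerate, normalized_heights

__all__ = [
    "ReferenceDistribution",
    "permute_rows",
    "reference_heights",
    "percentile",
    "qq_table",
]


@dataclass
class ReferenceDistribution:
    """Element-wise mean of r sorted, normalized replicate height vectors."""

    values: np.ndarray  # length n_s_used - 1, sorted non-decreasing
    r: int
    seed: int | None
    n_v_used: int
    n_s_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_s_used - 1:
            raise ValueError("reference vector must have length n_s - 1")
        if self.r < 1:
            raise ValueError("replicate count r must be >= 1")

    def __len__(self) -> int:
        return self.values.size


def permute_rows(Z: DataMatrix, rng: np.random.Generator) -> DataMatrix:
    """Reshuffle each row of Z independently and uniformly at random.

    Row means, standard deviations, and value multisets are preserved, so a
    standardized matrix stays standardized; only the pairing of values
    across rows (and hence any column grouping) is destroyed.
    """
    return Z.with_values(rng.permuted(Z.values, axis=1))


def reference_heights(
    Z: DataMatrix,
    r: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReferenceDistribution:
    """Build the reference distribution D_e from r row-permutation replicates.

    Each replicate reshuffles every row of Z, re-runs complete-linkage
    agglomeration, and records the sorted heights divided by sqrt(n_v).
    D_e is their element-wise mean.  In practice r = 10 already gives a
    stable reference; the Monte-Carlo variance of each element decays as 1/r.

    Pass either ``seed`` (preferred, recorded as provenance) or an existing
    ``rng`` stream.
    """
    if r < 1:
        raise ValueError(f"replicate count r must be >= 1, got {r}")
    if not Z.standardized:
        raise ValueError("Z must be standardized before building the reference")
    if rng is None:
        rng = np.random.default_rng(seed)
    # mean computed as first + mean(deviations): numerically shifted so that
    # identical replicates (e.g. n_s = 2, where row permutation cannot change
    # the single inter-column distance) average to themselves exactly
    first = None
    acc = np.zeros(Z.n_s - 1)
    for _ in range(r):
        Zi = permute_rows(Z, rng)
        h = normalized_heights(agglomerate(Zi), Z.n_v).values
        if first is None:
            first = h
        else:
            acc += h - first
    return ReferenceDistribution(
        values=first + acc / r, r=r, seed=seed, n_v_used=Z.n_v, n_s_used=Z.n_s
    )


def percentile(ref: ReferenceDistribution, p: float) -> float:
    """p-th percentile of the reference heights, linear interpolation (type 7)."""
    if not (0.0 < p <= 100.0):
        raise ValueError(f"percentile p must be in (0, 100], got {p}")
    return float(np.percentile(ref.values, p))


def qq_table(D_o: MergeHeights, D_e: ReferenceDistribution) -> pd.DataFrame:
    """Rank-paired observed vs expected heights for a QQ-plot.

    Points on the diagonal mean the observed agglomeration is
    indistinguishable from reshuffled (cluster-free) data; an S-shape —
    small ranks below the diagonal, large ranks above — signals real
    clusters, whose members are closer and whose groups are farther apart
    than chance sorting produces.
    """
    obs = np.sort(np.asarray(D_o.values, dtype=float))
    exp = np.sort(np.asarray(D_e.values, dtype=float))
    if obs.size != exp.size:
        raise ValueError(
            f"observed ({obs.size}) and expected ({exp.size}) height vectors "
            "must have equal length"
        )
    return pd.DataFrame(
        {"rank": np.arange(1, obs.size + 1), "expected": exp, "observed": obs}
    )
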