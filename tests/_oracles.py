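"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or naive algorithms,
staying independent of the code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform


def naive_complete_linkage_heights(columns: np.ndarray) -> np.ndarray:
    """Merge heights of complete-linkage clustering by naive O(n^3) search.

    ``columns``: (n_v, n_s) matrix.  Repeatedly merges the pair of clusters
    with the smallest maximum pairwise Euclidean distance (ties by smallest
    index pair) and records the merge distances.  Starting from the same
    pairwise distances as any linkage implementation, every merge height is
    exactly one of them, so agreement can be asserted bitwise.
    """
    pts = [columns[:, j] for j in range(columns.shape[1])]
    dist = squareform(pdist(columns.T))
    clusters = [[j] for j in range(len(pts))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


def naive_partitions(n: int):
    """All set partitions of range(n), as label vectors."""
    if n == 0:
        yield []
        return
    for part in _partitions(list(range(n))):
        labels = [0] * n
        for ci, block in enumerate(part):
            for el in block:
                labels[el] = ci
        yield labels


def _partitions(elements):
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for smaller in _partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def exact_reference_mean(Z: np.ndarray, n_v_norm: int | None = None) -> np.ndarray:
    """Exact expectation of sorted normalized heights over all row permutations.

    Enumerates every combination of per-row permutations of the matrix Z
    (feasible only for tiny matrices), clusters each, and averages the
    sorted, sqrt(n_v)-normalized merge-height vectors.
    """
    n_v, n_s = Z.shape
    if n_v_norm is None:
        n_v_norm = n_v
    perms = list(itertools.permutations(range(n_s)))
    acc = np.zeros(n_s - 1)
    count = 0
    for combo in itertools.product(perms, repeat=n_v):
        M = np.vstack([Z[i, list(p)] for i, p in enumerate(combo)])
        h = np.sort(naive_complete_linkage_heights(M)) / np.sqrt(n_v_norm)
        acc += h
        count += 1
    return acc / count
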