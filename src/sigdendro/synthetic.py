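"""Multivariate-normal cluster scenarios with full seed control.

Each scenario draws n_c true mean profiles in n_v dimensions — the first
profile is the zero vector, the remaining n_c - 1 have iid N(0, sigma^2)
entries — and then simulates each sample column from a multivariate normal
with identity covariance centered at its cluster's profile.  sigma controls
only the separation between cluster centers; observation noise is always
unit.  Cluster sizes are drawn from a symmetric Dirichlet(1)-weighted
multinomial with a minimum-size floor, giving the strongly unequal sizes
typical of real biomarker clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sigdendro.io import DataMatrix

__all__ = [
    "ScenarioConfig",
    "draw_profiles",
    "draw_cluster_sizes",
    "generate_dataset",
    "generate_null",
    "figure1_scenario",
]


@dataclass
class ScenarioConfig:
    """Parameters of one clustered-data scenario."""

    n_c: int  # number of true clusters
    n_v: int  # number of variables (profile dimension)
    n_s: int  # number of sample profiles (columns)
    sigma: float  # sd of the non-zero true-profile entries (center separation)
    min_cluster_size: int = 2
    max_cluster_size: int | None = None
    fixed_sizes: list[int] | None = None  # overrides the random size scheme
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_c < 1:
            raise ValueError("n_c must be >= 1")
        if self.n_v < 2:
            raise ValueError("n_v must be >= 2")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_s < self.n_c * self.min_cluster_size:
            raise ValueError(
                f"n_s={self.n_s} cannot hold {self.n_c} clusters of size "
                f">= {self.min_cluster_size}"
            )
        if self.fixed_sizes is not None:
            if len(self.fixed_sizes) != self.n_c or sum(self.fixed_sizes) != self.n_s:
                raise ValueError("fixed_sizes must have n_c entries summing to n_s")


def draw_profiles(n_c: int, n_v: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """True cluster mean profiles, shape (n_c, n_v); row 0 is the zero profile."""
    if n_c < 1:
        raise ValueError("n_c must be >= 1")
    profiles = np.zeros((n_c, n_v))
    if n_c > 1:
        profiles[1:] = rng.normal(0.0, sigma, size=(n_c - 1, n_v))
    return profiles


def draw_cluster_sizes(
    n_c: int,
    n_s: int,
    rng: np.random.Generator,
    min_size: int = 2,
    max_size: int | None = None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Dirichlet(1)-multinomial cluster sizes, resampled until constraints hold."""
    if n_c == 1:
        return np.array([n_s])
    for _ in range(max_tries):
        w = rng.dirichlet(np.ones(n_c))
        sizes = rng.multinomial(n_s, w)
        if sizes.min() >= min_size and (max_size is None or sizes.max() <= max_size):
            return sizes
    raise RuntimeError(
        f"could not draw {n_c} cluster sizes summing to {n_s} within the "
        f"[{min_size}, {max_size}] constraints"
    )


def generate_dataset(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Simulate one clustered data set.

    Returns ``(X, true_labels, profiles)`` where X is the n_v x n_s
    :class:`DataMatrix` (columns grouped by cluster), ``true_labels`` the
    generating assignment (1..n_c), and ``profiles`` the n_c x n_v matrix
    of true cluster means.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    profiles = draw_profiles(cfg.n_c, cfg.n_v, cfg.sigma, rng)
    if cfg.fixed_sizes is not None:
        sizes = np.asarray(cfg.fixed_sizes)
    else:
        sizes = draw_cluster_sizes(
            cfg.n_c, cfg.n_s, rng, cfg.min_cluster_size, cfg.max_cluster_size
        )
    labels = np.repeat(np.arange(1, cfg.n_c + 1), sizes)
    means = profiles[labels - 1]  # (n_s, n_v)
    values = (means + rng.standard_normal((cfg.n_s, cfg.n_v))).T
    X = DataMatrix(values)
    return X, labels, profiles


def generate_null(
    n_v: int, n_s: int, sigma: float = 1.0, rng: np.random.Generator | None = None
) -> DataMatrix:
    """One-cluster data: n_s columns iid multivariate normal(0, sigma^2 I).

    sigma is immaterial once rows are standardized; it is kept so the null
    generator mirrors the clustered one.
    """
    if rng is None:
        rng = np.random.default_rng()
    return DataMatrix(rng.normal(0.0, sigma, size=(n_v, n_s)))


def figure1_scenario(seed: int | None = None):
    """The reference worked scenario: 2000 profiles, 16 variables, 13 clusters.

    Profiles are separated by N(0, 4) cluster means (sigma = 2) and cluster
    sizes are constrained to the range 2..532.  Returns ``(X, true_labels)``.
    """
    cfg = ScenarioConfig(
        n_c=13,
        n_v=16,
        n_s=2000,
        sigma=2.0,
        min_cluster_size=2,
        max_cluster_size=532,
        seed=seed,
    )
    X, labels, _ = generate_dataset(cfg)
    return X, labels
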