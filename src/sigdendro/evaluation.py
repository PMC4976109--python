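"""Calibration and power studies for the detection procedure.

Two studies mirror the evaluation design of the method:

* the false-positive (calibration) study draws one-cluster data sets over a
  grid of dimensions and checks that the proportion of falsely detected
  clusters matches the nominal alpha of each percentile cut;
* the true-positive (power) study draws clustered data sets over a grid of
  (n_c, n_v, n_s, sigma) and scores each detection with the cluster-count
  error (PWC) and the two agreement indices.

Both also run the Beale pseudo-F scan as a classical comparator.  Default
problem sizes are desk scale — a few hundred data sets with up to ~1500
samples each — chosen so a study completes in minutes on one core while
Monte-Carlo standard errors remain small enough to see the calibration and
the power trends; the full-scale design (10,000 data sets per arm, up to
5000 samples) is reproduced by passing the corresponding arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sigdendro.beale import beale_select
from sigdendro.detection import detect_scan
from sigdendro.io import standardize_rows
from sigdendro.linkage import agglomerate
from sigdendro.metrics import contingency, cramers_v, jaccard_similarity, pwc
from sigdendro.synthetic import ScenarioConfig, generate_dataset, generate_null

__all__ = ["run_fpr_study", "run_tpr_study", "summarize", "dataset_seeds"]

DEFAULT_PERCENTILES = (95.0, 97.5, 99.0, 99.5, 99.9)


def dataset_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-dataset seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _col(name: str, p: float) -> str:
    return f"{name}_p{p:g}"


def run_fpr_study(
    n_datasets: int = 200,
    percentiles=DEFAULT_PERCENTILES,
    r: int = 10,
    seed: int = 0,
    n_v_range: tuple[int, int] = (2, 20),
    n_s_range: tuple[int, int] = (300, 1000),
    sigmas=(2.0, 5.0, 10.0),
    beale_alphas=(0.05, 0.001),
    beale_k_max: int = 500,
    run_beale: bool = True,
) -> pd.DataFrame:
    """False-positive study on one-cluster (null) data.

    Each data set draws n_v ~ U{n_v_range}, n_s ~ U{n_s_range} and a noise
    sd from ``sigmas``, generates a single multivariate-normal cluster,
    runs detection at every percentile, and records the proportion of
    wrongly detected clusters PWC = (n_detected - 1)/(n_s - 1).  With a
    calibrated procedure E[PWC] at percentile p is 1 - p/100.  Optionally
    the Beale scan is run at each ``beale_alphas`` level, recording whether
    it correctly selects a single cluster.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    percentiles = [float(p) for p in percentiles]
    seeds = dataset_seeds(seed, n_datasets)
    records = []
    for ds_seed in seeds:
        rng = np.random.default_rng(ds_seed)
        n_v = int(rng.integers(n_v_range[0], n_v_range[1] + 1))
        n_s = int(rng.integers(n_s_range[0], n_s_range[1] + 1))
        sigma = float(rng.choice(np.asarray(sigmas, dtype=float)))
        X = generate_null(n_v, n_s, sigma, rng)
        rec = {"n_c": 1, "n_v": n_v, "n_s": n_s, "sigma": sigma, "seed": ds_seed}
        results = detect_scan(X, percentiles, r=r, seed=ds_seed)
        for p, res in results.items():
            rec[_col("n_detected", p)] = res.n_clusters
            rec[_col("pwc", p)] = pwc(res.n_clusters, 1, n_s)
        if run_beale:
            Z = standardize_rows(X)
            d = agglomerate(Z)
            for a in beale_alphas:
                scan = beale_select(d, Z, alpha=a, k_max=beale_k_max, with_labels=False)
                rec[f"beale_k_alpha{a:g}"] = scan.k_selected
                rec[f"beale_one_alpha{a:g}"] = scan.k_selected == 1
                rec[f"beale_pwc_capped_alpha{a:g}"] = pwc(
                    scan.k_selected, 1, n_s, denominator_cap=beale_k_max
                )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def run_tpr_study(
    n_datasets: int = 300,
    sigmas=(2.0, 5.0, 10.0),
    percentiles=DEFAULT_PERCENTILES,
    r: int = 10,
    seed: int = 0,
    n_c_range: tuple[int, int] = (2, 20),
    n_v_range: tuple[int, int] = (2, 20),
    n_s_range: tuple[int, int] = (300, 1500),
    beale_alpha: float = 0.05,
    beale_k_max: int = 500,
    run_beale: bool = True,
) -> pd.DataFrame:
    """True-positive study on clustered grid data.

    Each data set draws (n_c, n_v, n_s) uniformly from the given ranges and
    sigma from ``sigmas``, simulates the clusters, and scores the detection
    at every percentile with the detected count, PWC, the Cramer's-V
    dependency index and the Jaccard similarity against the generating
    labels (the dependency index is NaN when it is undefined, i.e. when a
    partition collapses to one cluster).
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    percentiles = [float(p) for p in percentiles]
    seeds = dataset_seeds(seed, n_datasets)
    records = []
    for ds_seed in seeds:
        rng = np.random.default_rng(ds_seed)
        n_c = int(rng.integers(n_c_range[0], n_c_range[1] + 1))
        n_v = int(rng.integers(n_v_range[0], n_v_range[1] + 1))
        lo = max(n_s_range[0], 2 * n_c)
        n_s = int(rng.integers(lo, n_s_range[1] + 1))
        sigma = float(rng.choice(np.asarray(sigmas, dtype=float)))
        cfg = ScenarioConfig(n_c=n_c, n_v=n_v, n_s=n_s, sigma=sigma)
        X, truth, _ = generate_dataset(cfg, rng)
        rec = {"n_c": n_c, "n_v": n_v, "n_s": n_s, "sigma": sigma, "seed": ds_seed}
        results = detect_scan(X, percentiles, r=r, seed=ds_seed)
        for p, res in results.items():
            rec[_col("n_detected", p)] = res.n_clusters
            rec[_col("correct", p)] = res.n_clusters == n_c
            rec[_col("pwc", p)] = pwc(res.n_clusters, n_c, n_s)
            rec[_col("jaccard", p)] = jaccard_similarity(truth, res.labels)
            tab = contingency(truth, res.labels)
            rec[_col("cramers_v", p)] = (
                cramers_v(tab) if tab.r >= 2 and tab.c >= 2 else np.nan
            )
        if run_beale:
            Z = standardize_rows(X)
            d = agglomerate(Z)
            scan = beale_select(d, Z, alpha=beale_alpha, k_max=beale_k_max, with_labels=False)
            rec["beale_k"] = scan.k_selected
            rec["beale_correct"] = scan.k_selected == n_c
            rec["beale_pwc_capped"] = pwc(
                scan.k_selected, n_c, n_s, denominator_cap=beale_k_max
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize(records: pd.DataFrame, group_by=None) -> pd.DataFrame:
    """Grouped means, quartiles and Monte-Carlo standard errors of a study.

    Summarizes every numeric result column (scenario parameters and seeds
    excluded) with count, mean, SE of the mean, and quartiles.  With
    ``group_by=None`` a single overall row is returned.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    meta = {"n_c", "n_v", "n_s", "sigma", "seed"}
    data = records.copy()
    for c in data.columns:
        if data[c].dtype == bool:
            data[c] = data[c].astype(float)
    value_cols = [
        c
        for c in data.columns
        if c not in meta
        and (group_by is None or c not in set(group_by))
        and pd.api.types.is_numeric_dtype(data[c])
    ]

    def agg(frame: pd.DataFrame) -> pd.Series:
        out = {"n_records": len(frame)}
        for c in value_cols:
            x = frame[c].dropna()
            out[f"{c}_mean"] = x.mean()
            out[f"{c}_se"] = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan
            out[f"{c}_q25"] = x.quantile(0.25)
            out[f"{c}_q50"] = x.quantile(0.50)
            out[f"{c}_q75"] = x.quantile(0.75)
        return pd.Series(out)

    if group_by:
        grouped = data.groupby(list(group_by), sort=True)
        return grouped.apply(agg, include_groups=False).reset_index()
    return agg(data).to_frame().T
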