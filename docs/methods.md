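# Methods

This note records what `sigdendro` computes, the defaults it ships with
and why, and the limitations we know about. Notation: a data matrix has
`n_v` variables in rows and `n_s` samples in columns; `D` (or `n_s`) is
the number of samples, `n_c` the number of generating clusters.

## 1. Detection procedure

**Standardization.** Each variable (row) is centered and scaled to unit
SD (`ddof=1`). A trimmed variant (`method="trimmed"`) computes the mean
and SD after symmetrically discarding a fraction of extreme values per
row (default 5%) but still transforms *all* values; it is offered for
heavy-tailed data. Constant rows are rejected with an error naming the
variable, since they carry no distance information after scaling.

**Linkage.** Samples are clustered by agglomerative complete linkage on
Euclidean distance (`scipy.cluster.hierarchy.linkage`). Complete linkage
is the only method supported: its merge heights are genuine pairwise
distances (the diameter of the merged group), which makes the height
distribution interpretable and the permutation reference meaningful.

**Height normalization.** The `n_s − 1` merge heights are sorted and
divided by `sqrt(n_v)`. Under standardization, the expected squared
Euclidean distance between two unrelated samples grows linearly in
`n_v`; dividing by `sqrt(n_v)` puts heights from matrices with different
numbers of variables on a common scale (for two standardized, independent
samples the typical normalized distance is near `sqrt(2)`).

**Permutation reference.** Each of `r` replicates independently permutes
the entries *within every row* of the standardized matrix. This preserves
each variable's marginal distribution exactly while destroying the
across-variable association that makes samples cluster. Each replicate is
clustered the same way; its sorted normalized heights are averaged rank
by rank across replicates to give the reference distribution `D_e` — the
merge-height profile expected from these margins when no clusters exist.

*Default `r = 10`.* The reference is an average of `n_s − 1`-point order
statistics, so even a handful of replicates gives a stable rank-wise
mean; `r = 10` keeps a full detection run at roughly 11 linkage
computations. Increasing `r` tightens the reference but changes results
little beyond the third digit in our studies.

**QQ comparison.** `qq_table` pairs `D_o` and `D_e` rank by rank.
Clustered data push the bulk of observed heights *below* the diagonal
(within-cluster merges are tighter than chance) and leave a small number
of large observed heights standing clear of the reference's upper range —
these are the merges that join distinct groups.

**Cut rule.** The observed dendrogram (on the normalized height scale) is
cut at the `p`-th percentile of `D_e`; clusters are the branches below the
cut, so `n_clusters = 1 + #{D_o > threshold}`. The percentile is the
standard linear-interpolation definition (`numpy.percentile`, type 7).
The cut has significance level `alpha = 1 − p/100`: each merge height on
cluster-free data exceeds the threshold with probability ≈ `alpha`, so
`alpha` is the expected *proportion* of spurious extra clusters among the
`n_s − 1` possible splits. Default `p = 95`; `detect_scan` evaluates many
percentiles against a single shared reference and a single observed tree,
which is how a percentile sweep (e.g. `99.0:99.9:0.1`) should be run.

Cluster labels are canonical: numbered 1..k by decreasing size, ties
broken by first appearance in column order.

## 2. Agreement metrics

Given true labels (r classes) and inferred labels (c clusters) with
contingency table `n_ij`:

- **PWC** (proportional wrong-cluster count):
  `PWC = (c − r) / (D − r)`, the surplus of detected clusters as a
  fraction of the maximum possible surplus. 0 is perfect; positive means
  over-splitting (on null data, its mean estimates the false-cluster
  rate); negative means merging true groups. An optional denominator cap
  (used when scoring the pseudo-F comparator, whose scan stops at
  `k_max = 500`) replaces `D − r` with `cap − r`.
- **I_C** (dependency index): `(χ² / n) / min(r−1, c−1)` with Pearson's
  chi-squared (no continuity correction). Note this is the *square* of
  the textbook Cramér's V; `cramers_v(tab, classic=True)` returns the
  square-rooted version. I_C = 1 whenever every inferred cluster is pure,
  even if the cluster count is wrong.
- **I_J** (averaged Jaccard): `Σ_ij (n_ij / q_ij) / max(r, c)` where
  `q_ij = row_i + col_j − n_ij` is the union size. Unlike I_C it
  penalizes both impurity and a wrong cluster count; 1 only for an exact
  match up to relabeling.

The three are reported together because they fail differently: see
`examples/03_agreement_metrics.py`.

## 3. Beale pseudo-F comparator

As a classical baseline for choosing the number of clusters, the package
scans the nested cuts of the same complete-linkage dendrogram for
`k = 2 .. min(k_max, n_s − 1)` (default `k_max = 500`) and computes
Beale's pseudo-F for each partition against the one-cluster null:

```
F(k) = ((S1 − S2) / S2) / ( ((n_s − 1)/(n_s − k)) · k^(2/n_v) − 1 )
```

with `S1` the total within-group sum of squares for one cluster, `S2` for
`k` clusters, referred to an F distribution with `df1 = n_v (k − 1)` and
`df2 = n_v (n_s − k)`. The scan selects the `k` with the largest F whose
p-value is below `alpha` (ties go to the smaller `k`), or 1 cluster if
nothing is significant.

The scan is O(`n_s · n_v`) after linkage: each dendrogram merge's
contribution to the within-group sum of squares is computed bottom-up
from per-node counts, sums and sums of squares, and `S2(k)` is obtained
by a cumulative sum over merges (clipped at 0 against floating-point
cancellation).

## 4. Synthetic scenario generator

`generate_dataset(ScenarioConfig(n_c, n_v, n_s, sigma, ...))` draws:

- **Profiles:** cluster 1 has the zero profile; each remaining cluster's
  profile is iid `N(0, sigma²)` per variable. `sigma` is therefore the
  *separation* knob: larger `sigma` spreads cluster centers further apart
  relative to the unit-variance noise.
- **Sizes:** cluster proportions are Dirichlet(1) (uniform on the
  simplex), converted to counts by a multinomial draw and resampled until
  every cluster has at least `min_cluster_size = 2` members (and at most
  `max_cluster_size` when set). This yields realistically *unbalanced*
  clusters, including rare ones near the minimum size.
- **Data:** each sample is its cluster profile plus iid `N(0, 1)` noise
  (identity covariance). `generate_null` is the `n_c = 1` special case.

`figure1_scenario(seed)` pins a large benchmark configuration used
throughout the validation suite: 13 clusters, 16 variables, 2000 samples,
profile SD 2, cluster sizes between 2 and 532. Because profiles are drawn
at random, different seeds produce benchmarks of genuinely different
difficulty (see §6).

Per-dataset seeds in batch studies are spawned from the master seed with
`numpy.random.SeedSequence` and reduced mod 2³¹ so they remain valid
inputs everywhere.

## 5. Numerical choices

- Rank-wise averaging of the reference uses a shifted mean
  (`first + mean(deviations)`) so that when all replicates are identical
  — as they necessarily are at `n_s = 2`, where permutation cannot change
  the single distance — the reference equals the observed heights *bit
  for bit*, and the degenerate case is exactly calibrated.
- Merge heights, thresholds and cuts all live on the normalized
  (`/sqrt(n_v)`) scale; the observed tree is rescaled once rather than
  rescaling the threshold, so exported trees and labels are consistent.
- `fcluster(..., criterion="distance")` groups leaves whose merge height
  is ≤ the threshold, matching the cut rule `n_clusters = 1 + #{D_o >
  threshold}` exactly.

## 6. Known limitations

- **Extreme-percentile calibration bias.** The threshold is an empirical
  percentile of a vector of `m = n_s − 1` averaged order statistics. For
  cut percentile `p`, the expected exceedance proportion on null data is
  approximately `1 − k*/(m + 1)` with `k* = 1 + (m − 1)·p/100`, not
  exactly `1 − p/100`. At `p = 95` the difference is negligible, but at
  `p = 99` and especially `p = 99.9` with `n_s` in the hundreds, the
  realized false-cluster rate sits measurably *above* nominal (e.g.
  ~0.00157 vs 0.001 over 200 null datasets). This is a property of the
  percentile-of-finite-sample construction itself, not of the
  implementation; users needing tight control at extreme `alpha` should
  increase `n_s` or treat `alpha` as approximate.
- **Benchmark variability.** On the pinned 13-cluster benchmark, whether
  all 13 clusters are recovered at `p = 95` depends strongly on the
  random profile draw: clusters whose profiles land close together, or
  clusters of size 2–3, are merged or missed on many seeds (typical
  detected counts 10–13, Jaccard 0.85–1.0). Single-seed showcase numbers
  from such a scenario should not be read as typical performance.
- **Pseudo-F variant sensitivity.** Several pseudo-F formulas circulate
  that differ in the penalty term and degrees of freedom. On null data
  the scan's failure modes (F growing with `k` up to the cap, driving the
  capped PWC toward 1) are robust across variants, but the *fraction* of
  null datasets where the comparator correctly returns one cluster is
  highly sensitive to the variant and to `n_s`; published figures for
  such scans are hard to match without knowing the exact formula used.
- **Scope.** Complete linkage + Euclidean distance only; the permutation
  scheme assumes exchangeability within rows (it tests association
  between variables, and is blind to structure encoded purely in one
  variable's ordering); the generator's identity noise covariance means
  correlated-noise regimes are untested territory.
- **Problem sizes.** The package targets desk-scale problems — up to a
  few thousand samples and tens of variables; a full detection at
  `n_s = 2000`, `r = 10` takes a few seconds. Nothing prevents larger
  runs, but linkage is O(n_s²) memory.
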