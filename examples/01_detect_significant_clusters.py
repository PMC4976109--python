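"""Detect statistically significant clusters in a simulated biomarker matrix.

Simulates 3 multivariate-normal clusters of sample profiles, runs the
resampling detection procedure at the 95th percentile of the permutation
reference, and prints the detected partition.
"""

import numpy as np

from sigdendro import ScenarioConfig, detect_clusters, generate_dataset, jaccard_similarity

cfg = ScenarioConfig(n_c=3, n_v=10, n_s=400, sigma=5.0, seed=7)
X, truth, _ = generate_dataset(cfg)

res = detect_clusters(X, p=95, r=10, seed=7)

print(f"true clusters:     {cfg.n_c}")
print(f"detected clusters: {res.n_clusters} at alpha = {res.alpha:.3f}")
print(f"cut height:        {res.threshold:.3f} (normalized scale)")
print(f"Jaccard agreement: {jaccard_similarity(truth, res.labels):.3f}")
sizes = np.bincount(res.labels)[1:]
print(f"cluster sizes:     {sizes.tolist()}")
# A Jaccard of 1.0 means the detected partition reproduces the generating
# one exactly; the cut height is the 95th percentile of merge heights seen
# in cluster-free (row-reshuffled) versions of the same data.
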