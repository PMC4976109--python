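"""Scoring an inferred partition: PWC, dependency index, Jaccard similarity.

Shows the complementary behavior of the three metrics on a case where two
true clusters are merged by an over-stringent cut: the cluster-count error
(PWC) goes negative, the chi-squared dependency index stays at 1 (samples
are still sorted correctly), and the Jaccard similarity drops.
"""

from sigdendro import contingency, cramers_v, jaccard_similarity, pwc

truth = [1, 1, 1, 2, 2, 2, 3, 3, 3]
merged = [1, 1, 1, 1, 1, 1, 2, 2, 2]  # clusters 1 and 2 merged
exact = [5, 5, 5, 6, 6, 6, 7, 7, 7]

for name, inferred in [("exact", exact), ("merged", merged)]:
    tab = contingency(truth, inferred)
    print(f"{name:8s} PWC = {pwc(tab.c, tab.r, tab.n):+.3f}  "
          f"I_C = {cramers_v(tab):.3f}  "
          f"I_J = {jaccard_similarity(truth, inferred):.3f}")
# exact:  all three metrics at their optima (0, 1, 1).
# merged: PWC < 0 flags under-detection, I_C = 1 shows the agglomeration
#         itself was right, I_J < 1 penalizes the wrong cluster count.
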