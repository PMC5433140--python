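"""Evaluate chromatin profiles against genomic annotations.

Plants a TSS-like annotation on the active-promoter profile, then computes
the 2x2 contingency fold-enrichment (ad/bc with a one-tail Fisher exact
p-value) of every profile against it, and the ROC recovery of the feature
from the active-promoter weight column. The target profile should show a
fold-enrichment far above 1 with a tiny p-value, and an AUC well above 0.5.
"""

import numpy as np

from chromnmf import (
    assign_profiles,
    contingency_enrichment,
    roc_recovery,
    simulate_annotations,
    simulate_matrix,
)

_, truth = simulate_matrix(n_bins=10000, seed=11)
truth = simulate_annotations(truth, target_profile=0, precision=0.9, seed=12)

n = len(truth.labels)
track = assign_profiles(
    truth.W0,
    bin_chroms=np.full(n, "chrS1", dtype=object),
    bin_starts=np.arange(n, dtype=np.int64) * 200,
    bin_ends=np.arange(1, n + 1, dtype=np.int64) * 200,
    profile_names=truth.library.names,
)

tss = truth.features["TSS"].expand(50)  # point features widened to +/- 50 bp
print(f"feature {tss.name!r}: {len(tss)} intervals\n")
print("profile    a      b     ratio      p          significant")
for e in contingency_enrichment(track, tss):
    print(f"{e.profile_name:8s} {e.a:5d} {e.b:6d}  {e.ratio:8.2f}  {e.p:10.2e}  {e.significant}")

*_, auc = roc_recovery(truth.W0[:, 0], track=track, feature=tss)
print(f"\nROC recovery of the TSS feature from the ActProm weights: AUC = {auc:.3f}")
print("(the annotation was planted on ActProm bins at 90% precision,")
print(" so ActProm is enriched and predictive while other profiles are not)")
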