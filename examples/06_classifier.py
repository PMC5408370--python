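"""The two-step diagnostic classifier: 0.1% prevalence filter, DL/10
pseudo-count log transform, per-fold lasso selection, unpenalized
logistic refit, leave-one-out ROC.
"""

import numpy as np

import pdmeta as m
from pdmeta.synthetic import plant_mid_abundance_effects

cfg = plant_mid_abundance_effects(
    m.CohortConfig(n_case=31, n_control=28, n_taxa=200, depth_mean=1e5, seed=5),
    n_planted=5, log2fc=2.0,
)
counts, metadata, truth = m.generate_taxon_profiles(cfg)
y = metadata["group"].to_numpy()

X, detection_limit = m.prepare_features(counts)
print(f"{X.shape[1]} taxa pass the 0.1% mean-abundance filter; "
      f"detection limit = {detection_limit:.2e} (pseudo-count DL/10)")

report = m.loo_evaluate(X, y, k=6)
print(f"\nLOO ROC-AUC = {report.auc:.3f}")
print(f"sensitivity = {report.sensitivity:.3f}, specificity = {report.specificity:.3f} "
      f"at score threshold {report.threshold}")
print(f"one-sided Mann-Whitney p on held-out scores = {report.mwu_p:.2e}")

print("\nwhole-data model features (signed weights; + = higher in cases):")
for fid, row in report.whole_data_features.iterrows():
    mark = "*" if fid in truth.planted_feature_ids else " "
    print(f" {mark} {fid}: {row.weight:+.2f}")
print("(* = taxa that actually carry a planted effect)")

rng = np.random.default_rng(0)
null_auc = np.mean([m.loo_evaluate(X, rng.permutation(y), k=6).auc for _ in range(3)])
print(f"\npermuted-label null AUC (mean of 3) = {null_auc:.3f}; "
      f"gap = {report.auc - null_auc:.3f}")
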