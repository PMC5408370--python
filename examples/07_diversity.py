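"""Alpha diversity and rarefaction: per-sample richness/Shannon/evenness
at a fixed rarefaction depth, and the pooled accumulation curve.
"""

import pdmeta as m

cfg = m.CohortConfig(n_case=15, n_control=15, n_taxa=200, depth_mean=2e4, seed=9)
counts, metadata, _ = m.generate_taxon_profiles(cfg)

alpha = m.alpha_diversity(counts, rarefy_depth=3000, seed=0)
merged = alpha.join(metadata["group"])
print("alpha diversity at 3000-read rarefaction (group means):")
print(merged.groupby("group")[["richness", "shannon", "evenness"]].mean().round(3).to_string())

pooled_total = int(counts.data.sum().sum())
depths = [1000, 10_000, 100_000, pooled_total]
curve = m.accumulation_curve(counts, depths, seed=0, n_repeats=10)
print("\npooled rarefaction curve (mean richness +/- SD):")
for d, row in curve.iterrows():
    print(f"  depth {d:>8}: {row.mean_richness:7.1f} +/- {row.sd_richness:.1f}")

acc = m.sample_accumulation(counts, seed=0, n_permutations=20)
print(f"\nsample-accumulation: {acc['mean_richness'].iloc[0]:.1f} taxa in 1 sample, "
      f"{acc['mean_richness'].iloc[-1]:.0f} after all {len(acc)} samples")
print("A plateauing curve means deeper sampling adds few new taxa.")
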