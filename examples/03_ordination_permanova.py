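"""Community-level contrast: Bray-Curtis distances, NMDS ordination,
PERMANOVA (4999 randomizations) and the betadisper dispersion check.
"""

import pdmeta as m
from pdmeta.synthetic import plant_mid_abundance_effects

cfg = plant_mid_abundance_effects(
    m.CohortConfig(n_case=30, n_control=28, n_taxa=200, depth_mean=1e5, seed=3),
    n_planted=10, log2fc=3.0,
)
counts, metadata, _ = m.generate_taxon_profiles(cfg)
groups = metadata["group"].to_numpy()

rarefied = m.rarefy(counts, depth=50_000, seed=0)
logged = m.tss_log_transform(rarefied)
dist = m.bray_curtis(logged)

ordination = m.nmds(dist, k=3, restarts=10, seed=0)
print(f"NMDS (k=3): stress-1 = {ordination.stress:.3f} over {ordination.n_restarts} starts")
print("(stress < 0.2 is conventionally an interpretable embedding)")

res = m.permanova(dist, groups, n_permutations=4999, seed=0)
print(f"\nPERMANOVA: pseudo-F = {res.pseudo_f:.2f}, R2 = {res.r2:.3f}, p = {res.p:.4f}")
print("R2 is the fraction of squared-distance variation explained by the case/control split.")

disp = m.dispersion_test(dist, groups, n_permutations=999, seed=0)
print(f"\nbetadisper: F = {disp.statistic:.2f}, p = {disp.p:.3f}, "
      f"group dispersions = { {k: round(v, 3) for k, v in disp.group_dispersions.items()} }")
print("betadisper separates location from spread: if it is also significant, part")
print("of the PERMANOVA signal may come from unequal group dispersion (here the")
print("planted fold-changes genuinely widen the case group's spread a little).")
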