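# Methods

This note documents the statistical procedures pdmeta implements, the
modelling choices behind the synthetic cohort generator, and the
numerical conventions that matter when reproducing results.

## Data model

Abundance matrices are features × samples, nonnegative, either integer
read counts or fractional marker-gene coverages. Each feature may carry
a seven-rank lineage (kingdom→species) plus an mOTU-style unit id. A
rank is either a name or the marker `unclassified <nearest classified
ancestor>`; once unclassified, all lower ranks are unclassified. At
aggregation time unclassified buckets stay distinct per parent taxon
("unclassified Firmicutes" is a different output feature from
"unclassified Bacteroidetes"), because partially classified units are
legitimate, reportable findings in marker-gene profiling.

`CountMatrix.transforms` records applied transforms in order; the
pipeline refuses to rarefy an already log-transformed matrix, since
rarefaction is only meaningful on counts.

Filters compare thresholds against the matrix's native scale: for read
counts the genus preset means "≥ 5 reads total", for fractional mOTU
coverages the same numbers apply to coverage units. Boundary semantics
are "strictly less than" for exclusion (a feature with total exactly 5
is kept) and "more than ten" for the absence rule (absent in 11 or more
samples is removed).

## Normalization and rarefaction

TSS + log: v → log10(v / sample_sum + 1). The transform is invertible
given the sample sums (round-trip tested to 1e-9 relative error).

Rarefaction draws exactly `depth` reads per sample **without
replacement** (multivariate hypergeometric), so rarefied column sums
equal the depth exactly and the expected rarefied count of a feature is
depth·(count/total). Samples below the depth are dropped with a
warning. The draw is deterministic under the supplied seed. No default
depth is claimed: it is a required argument of every rarefying
operation.

## Univariate testing

* Kruskal–Wallis per feature with midranks and the tie correction
  1 − Σ(t³−t)/(N³−N); p from the chi-square null with #groups − 1
  degrees of freedom; constant features get p = 1 and a degeneracy
  flag. BH q-values are computed over the feature set by the step-up
  rule q_(i) = min_{j≥i} m·p_(j)/j clipped at 1.
* Post-hoc Wilcoxon rank-sum tests run for all group pairs, but only
  for features whose **unadjusted** omnibus p is below the 0.2 gate;
  BH is then applied within the post-hoc family only. (Gating on the
  unadjusted p is a documented choice; the alternative — gating on q —
  would make the post-hoc family depend on the BH step.)
* The blocked test is a stratified two-sample rank test (van Elteren
  style): within each block observations get midranks, the first
  group's score sum is centred and scaled by its within-block
  permutation moments, and blocks are combined into one standardized
  scalar Z. The default p is two-sided asymptotic normal; a
  within-block Monte-Carlo permutation option exists for small
  samples. A block containing only one group contributes nothing; with
  a single block the statistic reduces exactly to the tie-corrected
  normal-approximation Wilcoxon test without continuity correction.
* Spearman screens use tie-handled rho (equivalently, Pearson of
  midranks) per feature × covariate with BH within each covariate.
  A constant covariate is rejected with an error naming it.
* Alpha diversity is computed after rarefaction: richness = nonzero
  features, Shannon H = −Σ p ln p, Pielou J = H/ln(richness) (missing
  when richness = 1). The pooled accumulation curve rarefies the pooled
  community to each requested depth; the sample-accumulation variant
  adds samples in random order.
* Reporting convention: "significant" means p < 0.05 **and** q < 0.1.

## Community analysis

Bray–Curtis d(x,y) = Σ|x−y| / Σ(x+y). NMDS minimizes Kruskal stress-1
with monotone (isotonic) regression via iterative majorization; the
implementation runs one classical-scaling start plus `restarts` random
starts (default 20; k defaults to 3) and returns the lowest-stress
configuration with a convergence flag. Stress-1 is invariant to
rotation, translation and global scaling of the dissimilarities (both
properties are tested).

PERMANOVA uses the sums of squared distances directly (Huygens): with a
groups and n samples, SS_total = Σ_{i<j} d²/n, SS_within summed per
group, pseudo-F = (SS_among/(a−1))/(SS_within/(n−a)), R² =
SS_among/SS_total. The permutation p includes the observed statistic in
numerator and denominator, p = (1+hits)/(1+B), so p ≥ 1/(B+1); the
default B = 4999 gives a floor of 2e-4. Permutations are drawn from an
explicit seed.

The dispersion (betadisper-style) test embeds the distance matrix by
principal coordinates, keeping negative-eigenvalue axes as imaginary
components. Each group's spatial median is the geometric median fitted
with all axes treated as real; reported distances subtract the
imaginary part, d² = d²_pos − d²_neg, clamped at zero (the standard
correction for non-Euclidean dissimilarities such as Bray–Curtis).
Group dispersions are compared by a permutation F on the distances.

## Metabolic modules

A module definition is an ordered list of alternative KO sets (the flat
file carries one line per alternative: `module_id TAB alt_index TAB
KO1,KO2,…[TAB name]`). Per sample and module:

1. coverage of every alternative = (KOs with abundance > 0)/(set size);
   KOs absent from the abundance matrix count as zeros;
2. the maximum-coverage alternative is selected — ties go to the larger
   median abundance, then to the earlier position in the file;
3. if the chosen coverage is **strictly greater than** the 30%
   threshold, module abundance is the median over *all* KOs of that
   alternative, zeros included; otherwise 0 (recorded as 0, not
   missing, so downstream rank tests keep sample alignment).

Including zero-abundance KOs in the median is deliberate: it makes the
coverage gate meaningful (a sparsely covered path cannot inherit a high
median from its few detected members). The estimator is exactly
homogeneous — scaling a sample's KO abundances by c scales module
abundance by c and leaves coverage unchanged — and was verified against
a brute-force enumerator on random instances.

Contribution tracing restricts the gene-level table (sample, KO, genus,
abundance) to the chosen alternative's KOs and reports each genus's
mass fraction; fractions sum to 1 where the module is present and are
flagged zero rows otherwise. Group-differential contributions are
tested per module × genus with a two-sample rank test on the per-sample
fractions (samples with the module present only; fewer than 2 present
samples per group skips the test) and BH across all performed tests.
The choice of a rank test on fractions is an implementation decision:
the compositional nature of shares means a genuine boost of one genus
necessarily depresses the others' shares, which the test treats as
separate hypotheses.

## Mobile elements

Only qseqid, sseqid and evalue of the tabular alignment are consumed.
Hits with e-value ≥ 1e-7 are discarded (strict inequality). Each read
counts once, attributed to its best-e-value subject with ties broken by
input order; reads whose subject has no class mapping are excluded with
a warning. Per-class counts are divided by the sample's **total
sequenced read count**, supplied as a sidecar table — not inferred from
the hits, since the denominator must include unmapped reads. The group
comparison is the two-sample rank test, or the blocked rank test when a
confounder column (e.g. statin use) is given; an optional Spearman
screen relates class loads to bacterial family abundances with BH.

## Classifier

Features are relative abundances of taxa with mean relative abundance
≥ 0.1%, transformed log10(x + DL/10) where DL is the smallest strictly
positive relative abundance among retained features (computed after
the filter). Selection fits L1-penalized logistic regression along an
increasing-C grid (10^−3…10^3, 31 points, liblinear) and stops at the
largest C yielding at most k nonzero weights (at least one); features
are ranked by |weight|. k defaults to 6 and is configurable. Constant
features are excluded from the design outright. The selected features
are refit without penalty, and evaluation is leave-one-out with both
steps re-run on every fold's training set, so the held-out sample can
never influence its own selection (enforced by a mutation test). AUC is
the Mann–Whitney concordance with ties counting ½ (identical to the
trapezoidal ROC area); sensitivity/specificity are read at held-out
probability 0.5; the Mann–Whitney p is one-sided (cases scored higher),
matching a directional diagnostic claim. A whole-data model supplies
the reportable feature list with signed weights, and
`feature_composition` decomposes rank-level features into their member
mOTUs by mean relative abundance.

## Synthetic cohorts

The generator exists to give every stage inputs with known truth; its
laws are artifact choices, recorded in `SyntheticTruth`, not biological
claims:

* per-taxon base relative abundances: log-normal, log-sd 2.0 — heavy
  tails reproduce the dominance structure of gut profiles (a few
  families holding ~half the mass);
* per-sample × taxon overdispersion: log-normal with log-sd 1.0 and
  mean 1 — between-subject variation of a magnitude (CV above 100%)
  typical for gut taxa; without it, planted fold-changes would make
  every null taxon systematically differential through compositional
  renormalization, and the generator would not emulate the noise a
  real cohort brings;
* planted effects multiply case-group expected abundances by 2^log2FC
  before renormalization. `plant_mid_abundance_effects` places effects
  in a base-abundance quantile band (default 40–80%): sub-dominant
  enough that closure spillover stays well below the noise floor,
  abundant enough to be detectable — matching where differential taxa
  sit in real case-control studies;
* library sizes: negative binomial around the configured mean (size
  20), counts multinomial given the library size;
* clinical metadata: motor-score (UPDRS III) truncated normal in cases
  and exactly 0 in controls, a shared gastrointestinal-symptom law,
  bilirubin near 0.23 ± 0.03, and medication flags drawn at the
  printed cohort rates (statin heavily control-skewed, anti-PD drugs
  case-only);
* KO tables: each (taxon, KO) pair of a binary gene-content matrix
  contributes the taxon's abundance (optionally with multiplicative
  log-normal noise); the parallel gene-level table retains each copy's
  taxon and genus for contribution tracing;
* mobile-element hits: per sample multinomial over {Plasmid, Prophage,
  Virus, no-hit}, the Virus rate multiplied by `virus_effect` in
  cases; a configurable fraction of hits receives e-values above the
  validity threshold so the filter is exercised.

What the generator does **not** emulate: phylogenetic correlation of
effects, longitudinal structure, sequencing error, or read-level data.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under a realistic abundance/noise regime,
not performance guarantees on any particular real cohort.

## Problem sizes and numerical conventions

Calibration and power checks use the study-like design throughout:
30 + 28 (or 30 + 30) samples, 200 taxa, 1e5 reads/sample; 200
replicates for null calibration, 25 seeds for planted-effect recovery,
50 seeds for mobile-element power, 100 random instances for the module
oracle. Calibration replicates use 199 permutations per PERMANOVA
(p-resolution 0.005 suffices at α = 0.05); contract checks of the
permutation floor use the full 4999. The classifier's permuted-label
null is the mean AUC over three label permutations per cohort: with
strongly structured data a single permutation's AUC has a standard
deviation of ~0.1, and averaging makes the real-vs-null gap a stable
quantity.

Degenerate inputs fail loudly: zero-sum samples, all-filtered matrices,
constant covariates, single-group blocks, groups of size 1, thresholds
outside [0,1]. Ties use midranks everywhere. All stochastic operations
take explicit seeds and share no global state.

## Known limitations

* The blocked test's asymptotic null is approximate for very small or
  very unbalanced strata; use the permutation option there.
* NMDS is a local optimizer; the restart scheme makes low-stress
  solutions likely, not guaranteed.
* Module definitions must be pre-flattened into alternative KO sets;
  the full KEGG boolean grammar (complexes, AND/OR nesting) is not
  parsed.
* The enrichment test on contribution shares treats genera as separate
  hypotheses although shares are compositional.
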