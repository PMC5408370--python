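"""Synthetic case-control metagenome cohorts.

Generates the inputs the analysis pipeline expects — a taxonomic count
matrix with lineage annotation, clinical metadata, a KO abundance matrix
induced by a taxon x gene-content matrix, and a mobile-element hit table
— with known planted effects, so every downstream stage can be tested
end to end without sequencing data.

The generative model is an artifact choice, not a claim about biology:

* per-taxon base relative abundances are log-normal (heavy-tailed
  dominance structure, as in real gut profiles);
* per-sample, per-taxon log-normal overdispersion on top of the base
  (between-subject variation; its log-sd ``taxon_noise_sigma`` defaults
  to 1.0, a realistic between-subject CV for gut taxa);
* case samples multiply planted taxa by 2**log2fc before renormalizing;
* library sizes are negative-binomial around ``depth_mean``;
* counts are multinomial given the library size.

Everything that was planted is recorded in :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import RANKS, UNCLASSIFIED, CountMatrix, TaxonomyLineage

# Table-1-style cohort moments used to simulate clinical metadata
_UPDRS_CASE = (12.6, 6.9)        # mean, sd; truncated at 0; controls identically 0
_GSRS = (2.8, 2.4)               # shared law for both groups
_BILIRUBIN = (0.23, 0.03)
_CASE_FLAG_RATES = {
    "amantadine": 26 / 31,
    "dopamine_agonist": 11 / 31,
    "MAO_inhibitor": 28 / 31,
    "L_DOPA": 0.0,
    "statin": 1 / 31,
    "metformin": 1 / 31,
    "acetylsalicylic_acid": 2 / 31,
    "antibiotic_recent": 3 / 31,
}
_CONTROL_FLAG_RATES = {
    "amantadine": 0.0,
    "dopamine_agonist": 0.0,
    "MAO_inhibitor": 0.0,
    "L_DOPA": 0.0,
    "statin": 11 / 28,
    "metformin": 3 / 28,
    "acetylsalicylic_acid": 7 / 28,
    "antibiotic_recent": 3 / 28,
}
_SMOKING_P = {"no": 0.32, "yes": 0.15, "ex": 0.53}

_PHYLA = (
    ("Firmicutes", "Clostridia", "Clostridiales", ("Ruminococcaceae", "Lachnospiraceae", "Erysipelotrichaceae")),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", ("Bacteroidaceae", "Prevotellaceae", "Rikenellaceae")),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", ("Verrucomicrobiaceae",)),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", ("Enterobacteriaceae",)),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", ("Bifidobacteriaceae",)),
)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic case-control cohort."""

    n_case: int = 31
    n_control: int = 28
    n_taxa: int = 200
    depth_mean: float = 1e5
    depth_dispersion: float = 20.0  # NB size parameter; larger = less overdispersed
    planted_taxa: tuple[tuple[int, float], ...] = ()  # (taxon index, log2 fold-change)
    base_log_mean: float = 0.0
    base_log_sigma: float = 2.0
    taxon_noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for idx, _ in self.planted_taxa:
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"planted taxon index {idx} out of range")


@dataclass
class SyntheticTruth:
    """Record of what the generator actually planted."""

    planted_taxa: tuple[tuple[int, float], ...] = ()
    planted_feature_ids: tuple[str, ...] = ()
    planted_modules: tuple[tuple[str, int], ...] = ()  # (module id, effect direction)
    planted_virus_effect: float = 1.0


def plant_mid_abundance_effects(
    config: CohortConfig,
    n_planted: int,
    log2fc: float,
    quantile_range: tuple[float, float] = (0.4, 0.8),
) -> CohortConfig:
    """Return a copy of ``config`` with effects planted on mid-abundance taxa.

    Differential taxa in case-control gut studies are typically
    sub-dominant: planting a fold-change on a dominant taxon makes every
    other relative abundance genuinely shift through compositional
    closure, while ultra-rare taxa sit at the detection limit.  This
    helper replays the base-abundance draw for ``config.seed`` and picks
    ``n_planted`` taxa uniformly from the given base-abundance quantile
    band (default: the 40-80% band), deterministically per seed.
    """
    from dataclasses import replace

    rng = np.random.default_rng(config.seed)
    base = rng.lognormal(config.base_log_mean, config.base_log_sigma, size=config.n_taxa)
    order = np.argsort(base)
    lo, hi = (int(q * config.n_taxa) for q in quantile_range)
    if hi - lo < n_planted:
        raise ValueError("quantile band too narrow for the requested number of planted taxa")
    chosen = rng.choice(order[lo:hi], size=n_planted, replace=False)
    return replace(config, planted_taxa=tuple((int(i), log2fc) for i in sorted(chosen)))


def _make_lineages(n_taxa: int, rng: np.random.Generator) -> dict[str, TaxonomyLineage]:
    """Assign each mOTU-style unit to a nested taxonomy with ~n/4 genera."""
    lineages: dict[str, TaxonomyLineage] = {}
    n_genera = max(2, n_taxa // 4)
    for i in range(n_taxa):
        g = i % n_genera
        phy = _PHYLA[g % len(_PHYLA)]
        fam = phy[3][g % len(phy[3])]
        if g % 11 == 10:  # a sprinkling of partially classified units
            genus = f"{UNCLASSIFIED} {fam}"
            species = f"{UNCLASSIFIED} {fam}"
        else:
            genus = f"{fam[:-4]}_{g:03d}"
            species = f"{genus} sp{i:04d}"
        lineages[f"motu_{i:04d}"] = TaxonomyLineage(
            "Bacteria", phy[0], phy[1], phy[2], fam, genus, species, unit=f"motu_{i:04d}"
        )
    return lineages


def _simulate_metadata(n_case: int, n_control: int, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"PD{i:03d}" for i in range(n_case)] + [f"CT{i:03d}" for i in range(n_control)]
    group = ["case"] * n_case + ["control"] * n_control
    n = n_case + n_control
    updrs = np.concatenate(
        [
            np.maximum(0.0, rng.normal(*_UPDRS_CASE, size=n_case)),
            np.zeros(n_control),
        ]
    )
    gsrs = np.maximum(0.0, rng.normal(*_GSRS, size=n))
    bili = np.maximum(0.01, rng.normal(*_BILIRUBIN, size=n))
    age = rng.normal(65.0, 10.0, size=n).round(0)
    md = pd.DataFrame(
        {"group": group, "age": age, "UPDRS_III": updrs, "GSRS": gsrs, "bilirubin": bili},
        index=pd.Index(ids, name="sample_id"),
    )
    for flag in _CASE_FLAG_RATES:
        p_case, p_ctl = _CASE_FLAG_RATES[flag], _CONTROL_FLAG_RATES[flag]
        md[flag] = np.concatenate(
            [rng.random(n_case) < p_case, rng.random(n_control) < p_ctl]
        )
    levels = np.array(list(_SMOKING_P))
    md["smoking"] = levels[rng.choice(len(levels), size=n, p=list(_SMOKING_P.values()))]
    return md


def generate_taxon_profiles(
    config: CohortConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a case-control taxonomic count matrix with planted effects.

    Returns the count matrix (features x samples), per-sample metadata
    and the truth record.  Same seed => bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    base = rng.lognormal(config.base_log_mean, config.base_log_sigma, size=config.n_taxa)
    for idx, _ in config.planted_taxa:
        if base[idx] == 0:
            raise ValueError(f"planted fold-change on zero-abundance taxon {idx}")

    fc = np.ones(config.n_taxa)
    for idx, log2fc in config.planted_taxa:
        fc[idx] = 2.0 ** log2fc

    md = _simulate_metadata(config.n_case, config.n_control, rng)
    is_case = (md["group"] == "case").to_numpy()

    sigma = config.taxon_noise_sigma
    # mean-1 multiplicative jitter so group means differ only by planted effects
    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=(config.n_taxa, n))
    expected = base[:, None] * noise
    expected[:, is_case] *= fc[:, None]
    probs = expected / expected.sum(axis=0, keepdims=True)

    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    depths = rng.negative_binomial(config.depth_dispersion, p_nb, size=n)
    depths = np.maximum(depths, 1)

    counts = np.empty((config.n_taxa, n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(depths[j], probs[:, j])

    lineages = _make_lineages(config.n_taxa, rng)
    feature_ids = list(lineages)
    data = pd.DataFrame(counts.astype(float), index=feature_ids, columns=md.index)
    truth = SyntheticTruth(
        planted_taxa=tuple(config.planted_taxa),
        planted_feature_ids=tuple(feature_ids[i] for i, _ in config.planted_taxa),
    )
    return CountMatrix(data=data, lineages=lineages), md, truth


def generate_gene_content(
    n_taxa: int, n_kos: int, density: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Random binary taxon x KO gene-content matrix."""
    rng = np.random.default_rng(seed)
    mat = (rng.random((n_taxa, n_kos)) < density).astype(int)
    return pd.DataFrame(
        mat,
        index=[f"motu_{i:04d}" for i in range(n_taxa)],
        columns=[f"K{j:05d}" for j in range(n_kos)],
    )


def generate_ko_matrix(
    profiles: CountMatrix,
    gene_content: pd.DataFrame,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KO abundances induced by taxon abundances through gene content.

    Each (taxon, KO) pair with indicator 1 contributes one gene whose
    abundance is the taxon abundance times multiplicative log-normal
    noise.  Returns ``(ko_matrix, gene_table)`` where ``ko_matrix`` is
    KOs x samples and ``gene_table`` has one row per
    (sample, KO, taxon) gene copy with its genus — the input to
    contribution tracing.
    """
    if list(gene_content.index) != list(profiles.feature_ids):
        raise ValueError("gene_content rows must match profile taxa")
    rng = np.random.default_rng(seed)
    taxa = np.asarray(profiles.feature_ids)
    kos = np.asarray(gene_content.columns)
    genus_of = {
        f: (profiles.lineages[f].genus if f in profiles.lineages else f) for f in taxa
    }

    t_idx, k_idx = np.nonzero(gene_content.to_numpy())
    abund = profiles.data.to_numpy()  # taxa x samples
    n_samples = abund.shape[1]
    gene_abund = abund[t_idx]  # gene copies (pairs) x samples
    if noise_sigma > 0:
        gene_abund = gene_abund * rng.lognormal(
            -0.5 * noise_sigma**2, noise_sigma, size=gene_abund.shape
        )
    ko_mat = np.zeros((len(kos), n_samples))
    np.add.at(ko_mat, k_idx, gene_abund)
    pi, sj = np.nonzero(gene_abund > 0)
    samples = np.asarray(profiles.sample_ids)
    genus_arr = np.asarray([genus_of[t] for t in taxa])
    gene_table = pd.DataFrame(
        {
            "sample": samples[sj],
            "ko": kos[k_idx[pi]],
            "taxon": taxa[t_idx[pi]],
            "genus": genus_arr[t_idx[pi]],
            "abundance": gene_abund[pi, sj],
        }
    )
    ko_df = pd.DataFrame(ko_mat, index=kos, columns=profiles.sample_ids)
    return ko_df, gene_table


MOBILE_CLASSES = ("Plasmid", "Prophage", "Virus")


def generate_mobile_hits(
    metadata: pd.DataFrame,
    class_rates: dict[str, float],
    total_reads: int,
    virus_effect: float = 1.0,
    invalid_fraction: float = 0.1,
    seed: int = 0,
):
    """Per-read mobile-element hit table with a planted case Virus effect.

    Per sample, per class, hit counts are multinomial over
    {Plasmid, Prophage, Virus, no-hit}; the Virus rate is multiplied by
    ``virus_effect`` in case samples.  ``invalid_fraction`` of the hits
    receive e-values above the 1e-7 validity threshold (they should be
    discarded downstream).
    """
    from .mobile import HitTable  # local import to avoid cycle

    rates = {c: float(class_rates.get(c, 0.0)) for c in MOBILE_CLASSES}
    if any(r < 0 for r in rates.values()):
        raise ValueError("class rates must be nonnegative")
    if sum(rates.values()) > 1:
        raise ValueError("class rates must sum to at most 1")
    rng = np.random.default_rng(seed)
    cols = {"sample": [], "read": [], "subject": [], "evalue": []}
    totals = {}
    for sid, row in metadata.iterrows():
        r = dict(rates)
        if row["group"] == "case":
            r["Virus"] *= virus_effect
        p = [r[c] for c in MOBILE_CLASSES]
        p.append(1.0 - sum(p))
        counts = rng.multinomial(total_reads, p)
        totals[sid] = total_reads
        read_no = 0
        for c, k in zip(MOBILE_CLASSES, counts[:3]):
            if k == 0:
                continue
            subj = rng.integers(0, 50, size=k)
            invalid = rng.random(k) < invalid_fraction
            # valid hits: log10(e) uniform in [-30, -7); invalid: [-7, -2]
            loge = np.where(
                invalid, rng.uniform(-7.0, -2.0, size=k), rng.uniform(-30.0, -7.0, size=k)
            )
            cols["sample"].append(np.full(k, sid, dtype=object))
            cols["read"].append(np.array([f"{sid}_read{read_no + i}" for i in range(k)]))
            cols["subject"].append(np.array([f"{c.lower()}:{s}" for s in subj]))
            cols["evalue"].append(10.0 ** loge)
            read_no += k
    hits = pd.DataFrame(
        {
            name: (np.concatenate(chunks) if chunks else np.array([], dtype=object))
            for name, chunks in cols.items()
        }
    )
    class_map = pd.Series(
        {f"{c.lower()}:{i}": c for c in MOBILE_CLASSES for i in range(50)}, name="class"
    )
    return HitTable(hits=hits, class_map=class_map, total_reads=pd.Series(totals, name="reads"))
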