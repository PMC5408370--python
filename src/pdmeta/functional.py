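"""KO-to-metabolic-module abundance estimation and contribution tracing.

A metabolic module (KEGG "M…" or gut-specific "MF…" style) is defined
as one or more alternative KO sets, each set one path through the
module.  Per sample, the alternative with the highest coverage
(fraction of its KOs detected, i.e. nonzero) is chosen; if that
coverage exceeds the 30% gate, module abundance is the median abundance
of *all* KOs of the chosen alternative (zeros included), otherwise 0.

Tie rules (deterministic): equal coverage -> larger median abundance ->
earlier position in the definition file.

Contribution tracing attributes each module's gene mass to genera and
tests, per module x genus, whether a genus's share differs between
case and control groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_adjust

__all__ = [
    "ModuleDefinition",
    "parse_module_definitions",
    "ModuleAbundanceTable",
    "module_abundance",
    "trace_contributions",
    "contribution_enrichment",
]


@dataclass(frozen=True)
class ModuleDefinition:
    """A module id with its ordered alternative KO sets."""

    module_id: str
    name: str
    alternatives: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError(f"module {self.module_id}: needs at least one alternative")
        for alt in self.alternatives:
            if not alt:
                raise ValueError(f"module {self.module_id}: empty alternative")
            if len(set(alt)) != len(alt):
                raise ValueError(f"module {self.module_id}: duplicate KO within an alternative")


def parse_module_definitions(path) -> list[ModuleDefinition]:
    """Read the flat definition file.

    One line per alternative: ``module_id<TAB>alt_index<TAB>KO1,KO2,…``
    with an optional fourth column carrying a human-readable name;
    ``#`` lines are comments.  A duplicated (module id, alternative
    index) pair is rejected, naming the id.
    """
    per_module: dict[str, list[tuple[int, tuple[str, ...]]]] = {}
    names: dict[str, str] = {}
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 tab-separated fields")
            mid, alt_s, kos_s = parts[0].strip(), parts[1].strip(), parts[2].strip()
            name = parts[3].strip() if len(parts) > 3 else ""
            try:
                alt_idx = int(alt_s)
            except ValueError:
                raise ValueError(f"line {lineno}: alternative index {alt_s!r} not an integer")
            kos = tuple(k.strip() for k in kos_s.split(",") if k.strip())
            if not kos:
                raise ValueError(f"line {lineno}: empty alternative for module {mid}")
            if (mid, alt_idx) in seen:
                raise ValueError(f"line {lineno}: duplicated module id {mid} (alternative {alt_idx})")
            seen.add((mid, alt_idx))
            per_module.setdefault(mid, []).append((alt_idx, kos))
            if name:
                names[mid] = name
    defs = []
    for mid, alts in per_module.items():
        alts.sort(key=lambda t: t[0])
        defs.append(
            ModuleDefinition(
                module_id=mid, name=names.get(mid, ""), alternatives=tuple(a for _, a in alts)
            )
        )
    return defs


def write_module_definitions(defs, path) -> None:
    """Inverse of :func:`parse_module_definitions`."""
    with open(path, "w") as fh:
        fh.write("# module_id\talternative_index\tKOs[\tname]\n")
        for d in defs:
            for i, alt in enumerate(d.alternatives):
                cols = [d.module_id, str(i), ",".join(alt)]
                if d.name:
                    cols.append(d.name)
                fh.write("\t".join(cols) + "\n")


@dataclass
class ModuleAbundanceTable:
    """Per sample x module: chosen alternative, coverage, abundance."""

    abundance: pd.DataFrame  # modules x samples
    coverage: pd.DataFrame  # coverage of the chosen alternative
    chosen_alternative: pd.DataFrame  # int index into ModuleDefinition.alternatives
    coverage_threshold: float


def module_abundance(
    ko_matrix: pd.DataFrame,
    definitions,
    coverage_threshold: float = 0.3,
) -> ModuleAbundanceTable:
    """Estimate module abundances from a KO x samples matrix.

    Per sample and module: coverage of every alternative = detected KOs
    / alternative size (KOs absent from the matrix count as zeros);
    choose the maximum-coverage alternative (ties: larger median, then
    earlier in file order); abundance = median over all its KOs if
    coverage > ``coverage_threshold``, else 0.
    """
    if not 0 <= coverage_threshold <= 1:
        raise ValueError("coverage threshold must lie in [0, 1]")
    samples = list(ko_matrix.columns)
    mids = [d.module_id for d in definitions]
    abund = pd.DataFrame(0.0, index=mids, columns=samples)
    cover = pd.DataFrame(0.0, index=mids, columns=samples)
    chosen = pd.DataFrame(0, index=mids, columns=samples, dtype=int)

    ko_index = {k: i for i, k in enumerate(ko_matrix.index)}
    X = ko_matrix.to_numpy(dtype=float)
    zeros = np.zeros(len(samples))

    for d in definitions:
        # alternative KO abundance blocks, missing KOs as zero rows
        blocks = []
        for alt in d.alternatives:
            rows = [X[ko_index[k]] if k in ko_index else zeros for k in alt]
            blocks.append(np.vstack(rows))
        covs = np.vstack([(b > 0).mean(axis=0) for b in blocks])  # alts x samples
        meds = np.vstack([np.median(b, axis=0) for b in blocks])
        # argmax with tie rules: coverage desc, median desc, index asc
        order = np.lexsort((np.arange(len(blocks))[:, None] * np.ones_like(covs),
                            -meds, -covs), axis=0)
        best = order[0]
        s_idx = np.arange(len(samples))
        best_cov = covs[best, s_idx]
        best_med = meds[best, s_idx]
        gated = best_cov > coverage_threshold
        abund.loc[d.module_id] = np.where(gated, best_med, 0.0)
        cover.loc[d.module_id] = best_cov
        chosen.loc[d.module_id] = best
    return ModuleAbundanceTable(
        abundance=abund, coverage=cover, chosen_alternative=chosen,
        coverage_threshold=coverage_threshold,
    )


def trace_contributions(
    gene_table: pd.DataFrame,
    definitions,
    coverage_threshold: float = 0.3,
    module_table: ModuleAbundanceTable | None = None,
) -> pd.DataFrame:
    """Taxonomic origin of module gene mass.

    ``gene_table`` rows carry (sample, ko, genus, abundance).  Per
    sample x module, gene mass is restricted to the KOs of the chosen
    alternative; the genus fraction is its mass share.  Samples where
    the module is gated out (abundance 0) get an all-zero, flagged row.

    Returns a long frame (sample, module, genus, fraction, present).
    """
    required = {"sample", "ko", "genus", "abundance"}
    if not required.issubset(gene_table.columns):
        raise ValueError(f"gene_table must have columns {sorted(required)}")
    if module_table is None:
        ko_matrix = gene_table.pivot_table(
            index="ko", columns="sample", values="abundance", aggfunc="sum", fill_value=0.0
        )
        module_table = module_abundance(ko_matrix, definitions, coverage_threshold)

    samples = list(module_table.abundance.columns)
    genera = sorted(gene_table["genus"].unique())
    by_sample_ko = gene_table.groupby(["sample", "ko", "genus"])["abundance"].sum()

    rows = []
    for d in definitions:
        for s in samples:
            present = module_table.abundance.at[d.module_id, s] > 0
            frac = dict.fromkeys(genera, 0.0)
            if present:
                alt = d.alternatives[int(module_table.chosen_alternative.at[d.module_id, s])]
                mass = {}
                for k in alt:
                    try:
                        sub = by_sample_ko.loc[(s, k)]
                    except KeyError:
                        continue
                    for genus, a in sub.items():
                        mass[genus] = mass.get(genus, 0.0) + float(a)
                total = sum(mass.values())
                if total > 0:
                    for genus, m in mass.items():
                        frac[genus] = m / total
                else:
                    present = False
            for genus in genera:
                rows.append((s, d.module_id, genus, frac[genus], present))
    return pd.DataFrame(rows, columns=["sample", "module", "genus", "fraction", "present"])


def contribution_enrichment(
    contributions: pd.DataFrame,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per module x genus, rank test of contribution fractions between groups.

    Only samples with the module present enter; a module with fewer
    than 2 present samples in either group is skipped (logged in the
    returned frame with p = NaN).  BH across all performed tests.
    """
    g = pd.Series(groups)
    labels = list(dict.fromkeys(g))
    if len(labels) != 2:
        raise ValueError("enrichment test requires exactly two groups")
    rows = []
    for (module, genus), sub in contributions.groupby(["module", "genus"], sort=True):
        sub = sub[sub["present"]]
        va = sub.loc[g.reindex(sub["sample"]).to_numpy() == labels[0], "fraction"].to_numpy()
        vb = sub.loc[g.reindex(sub["sample"]).to_numpy() == labels[1], "fraction"].to_numpy()
        if len(va) < 2 or len(vb) < 2:
            rows.append((module, genus, np.nan, np.nan, "skipped: <2 present per group"))
            continue
        if np.all(va == va[0] if len(va) else True) and np.all(vb == vb[0] if len(vb) else True) \
                and (len(va) and len(vb) and va[0] == vb[0]):
            u, p = len(va) * len(vb) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append((module, genus, u, p, ""))
    out = pd.DataFrame(rows, columns=["module", "genus", "statistic", "p", "note"])
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out
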