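"""Mobile-genetic-element quantification from alignment hit tables.

Consumes BLAST/DIAMOND tabular output (only qseqid, sseqid, evalue are
used) against a mobile-element database whose subjects carry one of the
classes Plasmid, Prophage or Virus.  Reads mapping with e-value
strictly below 1e-7 are valid hits; each read is counted once (best
e-value) and per-class counts are normalized by the sample's total
sequenced read count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import BlockedTestResult, bh_adjust, blocked_rank_test

CLASSES = ("Plasmid", "Prophage", "Virus")

__all__ = ["HitTable", "CLASSES", "quantify_mobile_elements", "compare_mobile_elements"]


@dataclass
class HitTable:
    """Per-read alignment hits plus the subject->class map and per-sample
    total read counts (the normalization denominator)."""

    hits: pd.DataFrame  # columns: sample, read, subject, evalue
    class_map: pd.Series  # subject id -> class
    total_reads: pd.Series  # sample id -> sequenced reads

    def __post_init__(self) -> None:
        required = {"sample", "read", "subject", "evalue"}
        if not required.issubset(self.hits.columns):
            raise ValueError(f"hit table must have columns {sorted(required)}")
        if len(self.hits) and (self.hits["evalue"] < 0).any():
            raise ValueError("negative e-values")
        if (self.total_reads <= 0).any():
            raise ValueError("total read counts must be positive")

    @classmethod
    def from_files(cls, blast_tab, class_map_tsv, read_counts_tsv) -> "HitTable":
        """Read outfmt-6-style tabular hits (qseqid sseqid pident length
        mismatch gapopen qstart qend sstart send evalue bitscore, with
        qseqid formatted ``sample|read``), a subject->class TSV and a
        sample->reads TSV."""
        tab = pd.read_csv(blast_tab, sep="\t", header=None, comment="#")
        qseq = tab.iloc[:, 0].astype(str)
        split = qseq.str.split("|", n=1, expand=True)
        hits = pd.DataFrame(
            {
                "sample": split[0],
                "read": qseq,
                "subject": tab.iloc[:, 1].astype(str),
                "evalue": tab.iloc[:, 10].astype(float),
            }
        )
        cmap = pd.read_csv(class_map_tsv, sep="\t", index_col=0).iloc[:, 0]
        totals = pd.read_csv(read_counts_tsv, sep="\t", index_col=0).iloc[:, 0]
        return cls(hits=hits, class_map=cmap, total_reads=totals)


def quantify_mobile_elements(hits: HitTable, evalue_threshold: float = 1e-7) -> pd.DataFrame:
    """Normalized per-class abundance (valid hits / total reads) per sample.

    Hits with e-value >= ``evalue_threshold`` are discarded; each read
    is counted once, attributed to its best-e-value subject (tie: first
    in input order); reads whose subject has no class are logged and
    excluded.  Returns samples x {Plasmid, Prophage, Virus}.
    """
    sample_index = list(hits.total_reads.index)
    out = pd.DataFrame(0.0, index=sample_index, columns=list(CLASSES))
    h = hits.hits
    h = h[h["evalue"] < evalue_threshold]
    if len(h):
        h = h.copy()
        h["_order"] = np.arange(len(h))
        # one hit per read: best e-value, ties broken by input order
        h = h.sort_values(["evalue", "_order"], kind="mergesort").drop_duplicates(
            subset=["sample", "read"], keep="first"
        )
        cls = h["subject"].map(hits.class_map)
        unresolved = cls.isna()
        if unresolved.any():
            warnings.warn(
                f"{int(unresolved.sum())} valid hits with unresolvable subject class excluded",
                stacklevel=2,
            )
            h, cls = h[~unresolved], cls[~unresolved]
        counts = pd.crosstab(h["sample"], cls)
        for c in CLASSES:
            if c in counts.columns:
                out.loc[counts.index, c] = counts[c].astype(float)
    return out.div(hits.total_reads.reindex(sample_index), axis=0)


def compare_mobile_elements(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    block: str | None = None,
    family_matrix=None,
    group_col: str = "group",
) -> dict:
    """Per-class case/control comparison.

    Two-sample Wilcoxon rank-sum per class; with ``block`` (a metadata
    column, e.g. statin use) the stratified blocked rank test is used
    instead.  If ``family_matrix`` (bacterial families x samples) is
    given, a Spearman screen of each class against each family is run
    with BH correction.

    Returns ``{"tests": DataFrame, "correlations": DataFrame | None}``.
    """
    md = metadata.loc[profiles.index]
    g = md[group_col].to_numpy()
    labels = list(dict.fromkeys(g))
    if len(labels) != 2:
        raise ValueError("comparison requires exactly two groups")
    rows = []
    for c in CLASSES:
        y = profiles[c].to_numpy(dtype=float)
        if block is not None:
            res: BlockedTestResult = blocked_rank_test(y, g, md[block].to_numpy())
            stat, p = res.statistic, res.p
        else:
            a, b = y[g == labels[0]], y[g == labels[1]]
            if np.all(y == y[0]):
                stat, p = len(a) * len(b) / 2.0, 1.0
            else:
                r = stats.mannwhitneyu(a, b, alternative="two-sided")
                stat, p = float(r.statistic), float(r.pvalue)
        rows.append(
            (c, stat, p, float(np.median(y[g == labels[0]])), float(np.median(y[g == labels[1]])))
        )
    tests = pd.DataFrame(
        rows, columns=["class", "statistic", "p", f"median_{labels[0]}", f"median_{labels[1]}"]
    ).set_index("class")

    correlations = None
    if family_matrix is not None:
        fam = family_matrix.data if hasattr(family_matrix, "data") else family_matrix
        fam = fam[profiles.index.intersection(fam.columns)]
        rows = []
        for c in CLASSES:
            y = profiles.loc[fam.columns, c].to_numpy(dtype=float)
            for f in fam.index:
                x = fam.loc[f].to_numpy(dtype=float)
                if np.all(x == x[0]) or np.all(y == y[0]):
                    rho, p = 0.0, 1.0
                else:
                    rho, p = stats.spearmanr(x, y)
                rows.append((c, f, rho, p))
        correlations = pd.DataFrame(rows, columns=["class", "family", "rho", "p"])
        correlations["q"] = bh_adjust(correlations["p"].to_numpy())
    return {"tests": tests, "correlations": correlations}
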