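"""Core data model for taxonomic abundance matrices.

Houses the :class:`CountMatrix` container (features x samples with full
lineage annotation), the rank-aggregation / feature-filtering /
normalization / rarefaction rules used throughout the pipeline, and the
Table-1-style cohort summary.

Conventions
-----------
Matrices are stored features-in-rows, samples-in-columns, matching the
TSV layout (first column = feature id, lineage string in a ``lineage``
side table).  Abundances may be integer read counts or fractional
marker-gene coverages; filters compare thresholds against whatever the
native scale is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

UNCLASSIFIED = "unclassified"


class EmptyResultError(ValueError):
    """Raised when a filtering step would silently yield an empty matrix."""


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ordered taxonomy from kingdom to species plus a unit id.

    A rank is either a proper name or the marker ``"unclassified <name of
    nearest classified ancestor>"``; once a rank is unclassified every
    lower rank must be unclassified too.
    """

    kingdom: str
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str
    unit: str = ""

    def __post_init__(self) -> None:
        seen_unclassified = False
        for name in self.names():
            is_uncl = name.startswith(UNCLASSIFIED)
            if seen_unclassified and not is_uncl:
                raise ValueError(
                    f"classified rank {name!r} below an unclassified rank in {self}"
                )
            seen_unclassified = seen_unclassified or is_uncl

    def names(self) -> tuple[str, ...]:
        return (
            self.kingdom,
            self.phylum,
            self.class_,
            self.order,
            self.family,
            self.genus,
            self.species,
        )

    def name_at(self, rank: str) -> str:
        try:
            return self.names()[RANKS.index(rank)]
        except ValueError:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None

    @classmethod
    def from_string(cls, s: str) -> "TaxonomyLineage":
        parts = [p.strip() for p in s.split(";")]
        names = []
        unit = ""
        for i, part in enumerate(parts):
            if i < 7:
                for pref in _PREFIXES:
                    if part.startswith(pref):
                        part = part[len(pref):]
                        break
                names.append(part)
            else:
                unit = part
        while len(names) < 7:
            parent = names[-1] if names else "Bacteria"
            base = parent.removeprefix(UNCLASSIFIED + " ")
            names.append(f"{UNCLASSIFIED} {base}")
        return cls(*names, unit=unit)

    def to_string(self) -> str:
        s = ";".join(p + n for p, n in zip(_PREFIXES, self.names()))
        if self.unit:
            s += ";" + self.unit
        return s


@dataclass
class CountMatrix:
    """Samples x taxa abundance table (stored features x samples).

    ``transforms`` records what has been applied, in order; rarefaction
    of an already log-transformed matrix is refused.
    """

    data: pd.DataFrame
    lineages: dict[str, TaxonomyLineage] = field(default_factory=dict)
    transforms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("negative abundances are not allowed")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, extra_transform: str | None = None) -> "CountMatrix":
        transforms = self.transforms + ((extra_transform,) if extra_transform else ())
        lineages = {f: self.lineages[f] for f in data.index if f in self.lineages}
        return CountMatrix(data=data, lineages=lineages, transforms=transforms)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(
            0,
            "lineage",
            [self.lineages[f].to_string() if f in self.lineages else "" for f in out.index],
        )
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        df.columns.name = None
        lineages = {}
        if "lineage" in df.columns:
            raw = df.pop("lineage")
            lineages = {
                f: TaxonomyLineage.from_string(s)
                for f, s in raw.items()
                if isinstance(s, str) and s
            }
        return cls(data=df.astype(float), lineages=lineages)


def aggregate_to_rank(matrix: CountMatrix, rank: str) -> CountMatrix:
    """Sum feature abundances up to a taxonomic rank.

    Marker-gene abundances of all members of each name at ``rank`` are
    summed; unclassified buckets stay distinct per parent taxon.  Per
    sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [f for f in matrix.feature_ids if f not in matrix.lineages]
    if missing:
        raise ValueError(f"features without lineage annotation: {missing[:5]}")
    level = RANKS.index(rank)
    names = [matrix.lineages[f].name_at(rank) for f in matrix.feature_ids]
    agg = matrix.data.groupby(pd.Index(names, name="feature_id"), sort=True).sum()
    # representative truncated lineage per output feature
    new_lineages: dict[str, TaxonomyLineage] = {}
    for f, name in zip(matrix.feature_ids, names):
        if name in new_lineages:
            continue
        lin = matrix.lineages[f]
        vals = list(lin.names()[: level + 1])
        parent = vals[-1].removeprefix(UNCLASSIFIED + " ")
        vals += [f"{UNCLASSIFIED} {parent}"] * (7 - len(vals))
        new_lineages[name] = TaxonomyLineage(*vals)
    return CountMatrix(data=agg, lineages=new_lineages, transforms=matrix.transforms)


GENUS_PRESET = dict(min_total=5.0, max_absent=None, min_mean=None)
SPECIES_PRESET = dict(min_total=10.0, max_absent=10, min_mean=2.0)


def filter_features(
    matrix: CountMatrix,
    min_total: float | None = None,
    max_absent: int | None = None,
    min_mean: float | None = None,
    preset: str | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop low-abundance features.

    ``preset="genus"`` excludes taxa with a summed abundance below 5
    units over all samples; ``preset="species"`` additionally removes
    features absent in more than 10 samples or with mean abundance
    below 2.  Returns the kept matrix plus a removal log.
    """
    if preset is not None:
        params = {"genus": GENUS_PRESET, "family": GENUS_PRESET, "species": SPECIES_PRESET}
        if preset not in params:
            raise ValueError(f"unknown preset {preset!r}")
        chosen = params[preset]
        min_total = chosen["min_total"] if min_total is None else min_total
        max_absent = chosen["max_absent"] if max_absent is None else max_absent
        min_mean = chosen["min_mean"] if min_mean is None else min_mean

    total = matrix.data.sum(axis=1)
    absent = (matrix.data == 0).sum(axis=1)
    mean = matrix.data.mean(axis=1)

    reasons: dict[str, list[str]] = {f: [] for f in matrix.feature_ids}
    keep = pd.Series(True, index=matrix.data.index)
    if min_total is not None:
        bad = total < min_total
        keep &= ~bad
        for f in matrix.data.index[bad]:
            reasons[f].append(f"total {total[f]:g} < {min_total:g}")
    if max_absent is not None:
        bad = absent > max_absent
        keep &= ~bad
        for f in matrix.data.index[bad]:
            reasons[f].append(f"absent in {absent[f]} > {max_absent} samples")
    if min_mean is not None:
        bad = mean < min_mean
        keep &= ~bad
        for f in matrix.data.index[bad]:
            reasons[f].append(f"mean {mean[f]:g} < {min_mean:g}")

    if not keep.any():
        raise EmptyResultError("all features removed by the filter")
    removal_log = pd.DataFrame(
        [(f, "; ".join(r)) for f, r in reasons.items() if r],
        columns=["feature_id", "reason"],
    )
    return matrix.with_data(matrix.data.loc[keep]), removal_log


def tss_log_transform(matrix: CountMatrix) -> CountMatrix:
    """Total-sum scaling followed by log10(x + 1).

    Each value v becomes log10(v / sample_sum + 1).  Zero-sum samples
    are rejected by sample id.
    """
    if "log" in matrix.transforms:
        raise ValueError("matrix is already log-transformed")
    sums = matrix.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {list(zero.index)}")
    out = np.log10(matrix.data / sums + 1.0)
    m = matrix.with_data(out, extra_transform="tss")
    return replace(m, transforms=m.transforms + ("log",))


def rarefy(matrix: CountMatrix, depth: int, seed: int) -> CountMatrix:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    The draw is multivariate-hypergeometric per sample (column sums hit
    ``depth`` exactly); samples with fewer than ``depth`` reads are
    dropped with a warning.  Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if "log" in matrix.transforms:
        raise ValueError("cannot rarefy a log-transformed matrix")
    counts = matrix.data.round().astype(np.int64)
    if not np.allclose(counts.values, matrix.data.values):
        raise ValueError("rarefaction requires integer counts")
    rng = np.random.default_rng(seed)
    kept_cols = []
    out = {}
    dropped = []
    for s in counts.columns:
        col = counts[s].to_numpy()
        if col.sum() < depth:
            dropped.append(s)
            continue
        out[s] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(s)
    if dropped:
        warnings.warn(f"samples below depth {depth} dropped: {dropped}", stacklevel=2)
    if not kept_cols:
        raise EmptyResultError(f"no sample reaches depth {depth}")
    df = pd.DataFrame(out, index=counts.index)[kept_cols]
    return matrix.with_data(df.astype(float), extra_transform="rarefied")


# --------------------------------------------------------------- metadata

NUMERIC_FIELDS = ("age", "UPDRS_III", "GSRS", "bilirubin")
FLAG_FIELDS = (
    "amantadine",
    "dopamine_agonist",
    "MAO_inhibitor",
    "L_DOPA",
    "statin",
    "metformin",
    "acetylsalicylic_acid",
    "antibiotic_recent",
)


def format_count_pct(count: int, n: int) -> str:
    """``26 of 31 -> "26 [83.9%]"`` with half-away-from-zero rounding."""
    pct = Decimal(100 * count) / Decimal(n)
    pct = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{count} [{pct}%]"


def summarize_cohort(
    metadata: pd.DataFrame,
    group_col: str = "group",
    numeric_fields: Sequence[str] | None = None,
    flag_fields: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cohort characteristics table: per-group n, mean +/- SD for numeric
    fields with a rank-test p-value, and ``count [pct%]`` for flags.

    Raises on an empty group.
    """
    if group_col not in metadata.columns:
        raise ValueError(f"metadata lacks column {group_col!r}")
    groups = list(dict.fromkeys(metadata[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    by = {g: metadata[metadata[group_col] == g] for g in groups}
    for g, sub in by.items():
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
    if numeric_fields is None:
        numeric_fields = [f for f in NUMERIC_FIELDS if f in metadata.columns]
    if flag_fields is None:
        flag_fields = [f for f in FLAG_FIELDS if f in metadata.columns]

    rows = []
    rows.append({"field": "n", **{g: str(len(by[g])) for g in groups}, "p": np.nan})
    for f in numeric_fields:
        cell = {}
        for g in groups:
            v = by[g][f].astype(float)
            cell[g] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
        p = np.nan
        if len(groups) == 2:
            a, b = (by[g][f].astype(float) for g in groups)
            if a.nunique() > 1 or b.nunique() > 1:
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            else:
                p = 1.0
        rows.append({"field": f, **cell, "p": p})
    for f in flag_fields:
        cell = {g: format_count_pct(int(by[g][f].astype(bool).sum()), len(by[g])) for g in groups}
        rows.append({"field": f, **cell, "p": np.nan})
    if "smoking" in metadata.columns:
        for level in ("no", "yes", "ex"):
            cell = {
                g: format_count_pct(int((by[g]["smoking"] == level).sum()), len(by[g]))
                for g in groups
            }
            rows.append({"field": f"smoking_{level}", **cell, "p": np.nan})
    return pd.DataFrame(rows).set_index("field")
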