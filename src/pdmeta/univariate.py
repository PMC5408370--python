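"""Univariate differential-abundance and correlation testing.

Kruskal-Wallis per feature with Benjamini-Hochberg q-values, post-hoc
Wilcoxon rank-sum tests gated at omnibus P < 0.2, a stratified
(van Elteren-style) blocked rank test for confounder control, Spearman
correlations of taxa with clinical covariates, and alpha-diversity /
accumulation summaries on rarefied counts.

"Significant" follows the convention p < 0.05 and q < 0.1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CountMatrix, rarefy

__all__ = [
    "bh_adjust",
    "kruskal_wallis_all",
    "posthoc_pairwise",
    "BlockedTestResult",
    "blocked_rank_test",
    "spearman_covariates",
    "alpha_diversity",
    "accumulation_curve",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1; order-preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, CountMatrix) else matrix


def _group_arrays(groups) -> tuple[np.ndarray, list]:
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g))
    return g, labels


def kruskal_wallis_all(matrix, groups) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per feature, chi-square p
    (df = #groups - 1), BH q over the feature set.

    Constant features get p = 1 and are flagged degenerate.  Group
    medians and means are reported for direction.
    """
    df = _as_frame(matrix)
    g, labels = _group_arrays(groups)
    if len(g) != df.shape[1]:
        raise ValueError("group vector length must match number of samples")
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")

    X = df.to_numpy(dtype=float)
    n_feat, N = X.shape
    ranks = stats.rankdata(X, axis=1)
    mean_rank = (N + 1) / 2.0
    H = np.zeros(n_feat)
    for lab in labels:
        mask = g == lab
        n_g = mask.sum()
        rbar = ranks[:, mask].mean(axis=1)
        H += n_g * (rbar - mean_rank) ** 2
    H *= 12.0 / (N * (N + 1))
    # tie correction per feature
    correction = np.ones(n_feat)
    for i in range(n_feat):
        _, counts = np.unique(X[i], return_counts=True)
        ties = counts[counts > 1]
        if len(ties):
            correction[i] = 1.0 - np.sum(ties**3 - ties) / (N**3 - N)
    degenerate = correction <= 0  # all values identical
    H = np.where(degenerate, 0.0, H / np.where(degenerate, 1.0, correction))
    p = np.where(degenerate, 1.0, stats.chi2.sf(H, df=len(labels) - 1))
    out = pd.DataFrame({"feature_id": df.index, "statistic": H, "p": p})
    out["q"] = bh_adjust(out["p"].to_numpy())
    for lab in labels:
        mask = g == lab
        out[f"median_{lab}"] = np.median(X[:, mask], axis=1)
        out[f"mean_{lab}"] = X[:, mask].mean(axis=1)
    out["degenerate"] = degenerate
    return out.set_index("feature_id")


def posthoc_pairwise(matrix, groups, omnibus: pd.DataFrame, gate: float = 0.2) -> pd.DataFrame:
    """Wilcoxon rank-sum tests for every group pair, only for features
    whose omnibus (unadjusted) p is below ``gate``; BH across all
    post-hoc tests performed."""
    df = _as_frame(matrix)
    g, labels = _group_arrays(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    gated = omnibus.index[omnibus["p"] < gate]
    rows = []
    for f in gated:
        x = df.loc[f].to_numpy(dtype=float)
        for a, b in itertools.combinations(labels, 2):
            xa, xb = x[g == a], x[g == b]
            if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
                p = 1.0
                u = len(xa) * len(xb) / 2.0
            else:
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                u, p = res.statistic, res.pvalue
            rows.append((f, a, b, u, p))
    out = pd.DataFrame(rows, columns=["feature_id", "group_a", "group_b", "statistic", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


@dataclass
class BlockedTestResult:
    statistic: float  # standardized linear rank statistic (Z)
    p: float
    n_blocks_used: int
    method: str


def blocked_rank_test(
    values,
    groups,
    block,
    n_permutations: int | None = None,
    seed: int = 0,
) -> BlockedTestResult:
    """Stratified two-sample rank test (van Elteren style).

    Within each block, observations receive midranks; the sum of the
    first group's scores is standardized by its within-block permutation
    moments and the block contributions combined into one scalar Z.
    p is two-sided from the asymptotic normal null, or from
    ``n_permutations`` within-block label permutations when requested
    (recommended at small n).

    Blocks containing only one group contribute nothing; if every block
    is degenerate the test is rejected.
    """
    x = np.asarray(values, dtype=float)
    g, labels = _group_arrays(groups)
    b = np.asarray(block)
    if len(labels) != 2:
        raise ValueError("blocked test requires exactly two groups")
    if not (len(x) == len(g) == len(b)):
        raise ValueError("values, groups and block must have equal length")

    def _stat(gvec: np.ndarray) -> float:
        T = 0.0
        ET = 0.0
        VT = 0.0
        used = 0
        for blk in np.unique(b):
            m = b == blk
            gm = gvec[m]
            n1 = (gm == labels[0]).sum()
            n2 = (gm == labels[1]).sum()
            if n1 == 0 or n2 == 0:
                continue
            used += 1
            scores = stats.rankdata(x[m])
            nb = n1 + n2
            T += scores[gm == labels[0]].sum()
            ET += n1 * scores.mean()
            VT += n1 * n2 / (nb * (nb - 1)) * np.sum((scores - scores.mean()) ** 2)
        if used == 0:
            raise ValueError("every block lies entirely within one group")
        if VT == 0:
            return 0.0, used
        return (T - ET) / np.sqrt(VT), used

    z_obs, used = _stat(g)
    if n_permutations is None:
        p = 2.0 * stats.norm.sf(abs(z_obs))
        method = "asymptotic"
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        gp = g.copy()
        for _ in range(n_permutations):
            for blk in np.unique(b):
                m = np.flatnonzero(b == blk)
                gp[m] = gp[m][rng.permutation(len(m))]
            z_perm, _ = _stat(gp)
            if abs(z_perm) >= abs(z_obs) - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        method = "permutation"
    return BlockedTestResult(statistic=float(z_obs), p=float(min(p, 1.0)),
                             n_blocks_used=used, method=method)


def spearman_covariates(
    matrix,
    metadata: pd.DataFrame,
    covariates=("UPDRS_III", "GSRS", "bilirubin"),
) -> pd.DataFrame:
    """Tie-handled Spearman rho and p per feature x covariate, with BH
    correction applied separately within each covariate."""
    df = _as_frame(matrix)
    results = []
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} missing from metadata")
        y = metadata.loc[df.columns, cov].to_numpy(dtype=float)
        if np.all(y == y[0]):
            raise ValueError(f"covariate {cov!r} is constant")
        block = []
        for f in df.index:
            x = df.loc[f].to_numpy(dtype=float)
            if np.all(x == x[0]):
                rho, p = 0.0, 1.0
            else:
                rho, p = stats.spearmanr(x, y)
            block.append((f, cov, rho, p))
        sub = pd.DataFrame(block, columns=["feature_id", "covariate", "rho", "p"])
        sub["q"] = bh_adjust(sub["p"].to_numpy())
        results.append(sub)
    return pd.concat(results, ignore_index=True)


def alpha_diversity(matrix: CountMatrix, rarefy_depth: int, seed: int = 0) -> pd.DataFrame:
    """Per-sample richness, Shannon H (natural log) and Pielou evenness
    J = H / ln(richness) after rarefying to ``rarefy_depth``.

    J is reported missing when richness is 1.  Samples below the depth
    are dropped (with a warning, by :func:`rarefy`).
    """
    rare = rarefy(matrix, rarefy_depth, seed)
    out = []
    for s in rare.sample_ids:
        col = rare.data[s].to_numpy()
        nz = col[col > 0]
        richness = len(nz)
        p = nz / nz.sum()
        H = float(-(p * np.log(p)).sum())
        J = H / np.log(richness) if richness > 1 else np.nan
        out.append((s, richness, H, J))
    return pd.DataFrame(out, columns=["sample_id", "richness", "shannon", "evenness"]).set_index(
        "sample_id"
    )


def accumulation_curve(
    matrix: CountMatrix,
    depths,
    seed: int = 0,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Pooled rarefaction curve: all samples pooled into one community,
    rarefied to each depth ``n_repeats`` times; mean and SD richness.

    A depth exceeding the pooled total is rejected.
    """
    pooled = matrix.data.sum(axis=1).round().astype(np.int64).to_numpy()
    total = int(pooled.sum())
    depths = [int(d) for d in depths]
    too_deep = [d for d in depths if d > total]
    if too_deep:
        raise ValueError(f"depths exceed pooled total {total}: {too_deep}")
    rng = np.random.default_rng(seed)
    rows = []
    for d in depths:
        rich = []
        for _ in range(n_repeats):
            draw = rng.multivariate_hypergeometric(pooled, d)
            rich.append(int((draw > 0).sum()))
        rows.append((d, float(np.mean(rich)), float(np.std(rich, ddof=1)) if n_repeats > 1 else 0.0))
    return pd.DataFrame(rows, columns=["depth", "mean_richness", "sd_richness"]).set_index("depth")


def sample_accumulation(
    matrix: CountMatrix,
    seed: int = 0,
    n_permutations: int = 20,
) -> pd.DataFrame:
    """Species-accumulation over samples: mean number of distinct
    features observed after pooling 1..n samples in random order."""
    present = (matrix.data.to_numpy() > 0)
    n = present.shape[1]
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_permutations, n))
    for r in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(present.shape[0], dtype=bool)
        for j, s in enumerate(order):
            seen |= present[:, s]
            curves[r, j] = seen.sum()
    return pd.DataFrame(
        {
            "n_samples": np.arange(1, n + 1),
            "mean_richness": curves.mean(axis=0),
            "sd_richness": curves.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n),
        }
    ).set_index("n_samples")
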