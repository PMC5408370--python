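"""Two-step diagnostic classifier with leave-one-out evaluation.

Pipeline: (1) genera below 0.1% mean relative abundance are dropped;
(2) relative abundances are log10-transformed with a pseudo-count of
one-tenth of the detection limit (the smallest strictly positive
relative abundance in the retained table); (3) a lasso-penalized
logistic regression selects the top-k features by absolute weight;
(4) the selected features are refit in an unpenalized logistic model.

Evaluation is leave-one-out with feature selection performed de novo
inside every fold, so the held-out sample never influences its own
fold's selection.  Performance is summarized as ROC-AUC (rank
concordance, ties counting one half), sensitivity/specificity at the
0.5 probability operating point, and a one-sided Mann-Whitney p on the
held-out scores (cases expected to score higher).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .profiles import CountMatrix

__all__ = [
    "prepare_features",
    "select_features",
    "loo_evaluate",
    "roc_metrics",
    "ClassifierReport",
    "feature_composition",
]


def prepare_features(
    matrix,
    min_mean_relabund: float = 1e-3,
) -> tuple[pd.DataFrame, float]:
    """Filter + detection-limit log transform.

    Converts to relative abundances, drops features with mean relative
    abundance below ``min_mean_relabund`` (0.1%), then transforms every
    value to log10(x + DL/10) where DL is the smallest strictly
    positive relative abundance among the retained features.

    Returns (samples x features table, DL).
    """
    df = matrix.data if isinstance(matrix, CountMatrix) else matrix
    sums = df.sum(axis=0)
    if (sums == 0).any():
        raise ValueError(f"zero-sum samples: {list(sums.index[sums == 0])}")
    rel = df / sums
    keep = rel.mean(axis=1) >= min_mean_relabund
    if not keep.any():
        raise ValueError("all features fall below the mean-relative-abundance filter")
    rel = rel.loc[keep]
    positive = rel.to_numpy()[rel.to_numpy() > 0]
    dl = float(positive.min())
    X = np.log10(rel + dl / 10.0)
    return X.T, dl  # samples x features


def _lasso_path_fit(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Weights at the smallest penalty (largest C) with <= k nonzeros.

    Walks an increasing-C (decreasing-penalty) grid; the sparsest end
    has no features, the densest too many.  Stops at the last grid
    point with at most k nonzero weights, requiring at least one.
    """
    weights = np.zeros(X.shape[1])
    for C in np.logspace(-3, 3, 31):
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-8, random_state=0
        )
        clf.fit(X, y)
        w = clf.coef_.ravel()
        nnz = np.count_nonzero(w)
        if nnz > k:
            if np.count_nonzero(weights) == 0:
                weights = w  # even the densest-allowed point overshoots: fall back
            break
        if nnz >= 1:
            weights = w
    return weights


def select_features(X: pd.DataFrame, y, k: int = 6) -> pd.DataFrame:
    """Lasso-based top-k feature selection.

    Fits an L1-penalized logistic model along a decreasing-penalty path
    and returns up to ``k`` features ranked by absolute weight (fewer
    when the lasso zeroes more).  Deterministic given the data.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need two classes with at least 2 samples each")
    if k > X.shape[1]:
        warnings.warn(f"k={k} exceeds feature count {X.shape[1]}; returning all", stacklevel=2)
        k = X.shape[1]
    Xv = X.to_numpy(dtype=float)
    # constant columns carry no class information; with an intercept in
    # the model they could still absorb weight, so exclude them outright
    informative = Xv.std(axis=0) > 0
    w = np.zeros(Xv.shape[1])
    if informative.any():
        w[informative] = _lasso_path_fit(Xv[:, informative], y, k)
    order = np.argsort(-np.abs(w), kind="mergesort")
    order = [i for i in order if w[i] != 0][:k]
    return pd.DataFrame(
        {"feature_id": X.columns[order], "weight": w[order]}
    ).set_index("feature_id")


@dataclass
class ClassifierReport:
    fold_selections: list  # per held-out sample, the selected feature list
    scores: pd.Series  # held-out probability of the positive class
    labels: pd.Series
    auc: float
    sensitivity: float
    specificity: float
    mwu_p: float
    whole_data_features: pd.DataFrame = field(default_factory=pd.DataFrame)
    threshold: float = 0.5


def _fit_fold(X_train, y_train, k: int) -> tuple[list, LogisticRegression]:
    sel = select_features(X_train, y_train, k=k)
    features = list(sel.index)
    clf = LogisticRegression(C=np.inf, max_iter=5000)
    clf.fit(X_train[features].to_numpy(), y_train)
    return features, clf


def loo_evaluate(
    X: pd.DataFrame,
    y,
    k: int = 6,
    positive_label="case",
    threshold: float = 0.5,
) -> ClassifierReport:
    """Leave-one-out evaluation with de novo per-fold feature selection.

    For each sample i the lasso selection and the unpenalized refit use
    all samples except i; sample i is then scored.  Aggregates ROC-AUC,
    sensitivity/specificity at ``threshold``, and the one-sided
    Mann-Whitney p (positive class scored higher), plus the features a
    whole-data model selects.
    """
    y = pd.Series(np.asarray(y), index=X.index)
    if X.shape[0] < 6:
        raise ValueError("need at least 6 samples for leave-one-out evaluation")
    ybin = (y == positive_label).astype(int).to_numpy()
    if ybin.sum() == 0 or ybin.sum() == len(ybin):
        raise ValueError("both classes must be present")

    scores = {}
    fold_selections = []
    for i, sid in enumerate(X.index):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        if ybin[mask].sum() < 2 or (1 - ybin[mask]).sum() < 2:
            raise ValueError("a fold's training set lacks a class (degenerate n)")
        features, clf = _fit_fold(X.iloc[mask], ybin[mask], k)
        fold_selections.append(features)
        scores[sid] = float(clf.predict_proba(X.loc[[sid], features].to_numpy())[0, 1])
    scores = pd.Series(scores, name="score")

    auc, sens, spec = roc_metrics(scores.to_numpy(), ybin, threshold=threshold)
    pos, neg = scores.to_numpy()[ybin == 1], scores.to_numpy()[ybin == 0]
    if np.all(scores.to_numpy() == scores.iloc[0]):
        mwu_p = 1.0
    else:
        mwu_p = float(stats.mannwhitneyu(pos, neg, alternative="greater").pvalue)
    whole = select_features(X, ybin, k=k)
    return ClassifierReport(
        fold_selections=fold_selections,
        scores=scores,
        labels=y,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        mwu_p=mwu_p,
        whole_data_features=whole,
        threshold=threshold,
    )


def roc_metrics(scores, labels, threshold: float = 0.5) -> tuple[float, float, float]:
    """AUC as Mann-Whitney concordance (ties = 1/2) plus confusion-based
    sensitivity and specificity at ``threshold``."""
    s = np.asarray(scores, dtype=float)
    yb = np.asarray(labels).astype(int)
    pos, neg = s[yb == 1], s[yb == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[yb == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    sens = float((pos >= threshold).mean())
    spec = float((neg < threshold).mean())
    return float(auc), sens, spec


def feature_composition(motu_matrix: CountMatrix, rank: str = "genus") -> pd.DataFrame:
    """Decompose rank-level features into their member mOTUs.

    For each feature name at ``rank``, reports each member unit and the
    percentage of the feature's mean relative abundance it carries —
    the mapping-table join behind per-feature mOTU composition reports.
    """
    rel = motu_matrix.data / motu_matrix.data.sum(axis=0)
    mean_rel = rel.mean(axis=1)
    rows = []
    for f in motu_matrix.feature_ids:
        lin = motu_matrix.lineages[f]
        rows.append((lin.name_at(rank), f, mean_rel[f]))
    df = pd.DataFrame(rows, columns=[rank, "motu", "mean_relabund"])
    totals = df.groupby(rank)["mean_relabund"].transform("sum")
    df["pct_of_feature"] = np.where(totals > 0, 100 * df["mean_relabund"] / totals, 0.0)
    return df
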