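"""Between-sample community analysis.

Bray-Curtis dissimilarity, non-metric multidimensional scaling (NMDS,
Kruskal stress-1 with monotone regression), PERMANOVA with a seeded
label-permutation null (default 4999 randomizations), and a
betadisper-style test of homogeneity of group dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import smacof

from .profiles import CountMatrix

__all__ = [
    "bray_curtis",
    "OrdinationResult",
    "nmds",
    "PermanovaResult",
    "permanova",
    "DispersionResult",
    "dispersion_test",
]


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between samples."""
    df = matrix.data if isinstance(matrix, CountMatrix) else matrix
    X = df.to_numpy(dtype=float).T  # samples x features
    sums = X.sum(axis=1)
    if np.any(sums == 0):
        bad = [df.columns[i] for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"zero-sum samples: {bad}")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(df.columns))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1, minimum over restarts
    n_restarts: int
    seed: int
    converged: bool


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    """Classical-scaling start configuration (top-k positive axes)."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    w, v = np.linalg.eigh(G)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(lam)


def nmds(
    dist: DistanceMatrix,
    k: int = 3,
    restarts: int = 20,
    max_iter: int = 300,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Iterative majorization from ``restarts`` random starts plus one
    classical-scaling start; the best (lowest-stress) configuration is
    returned.  A warning flag is set when the best run hit ``max_iter``
    without meeting the convergence tolerance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n <= k:
        raise ValueError("need more samples than dimensions")
    rng = np.random.default_rng(seed)
    inits = [_pcoa_coords(d, k)]
    scale = d.mean() if d.mean() > 0 else 1.0
    inits += [rng.normal(scale=scale, size=(n, k)) for _ in range(restarts)]
    best = None
    for init in inits:
        coords, stress, n_iter = smacof(
            d,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=1e-8,
            normalized_stress=True,
            return_n_iter=True,
        )
        if best is None or stress < best[1]:
            best = (coords, stress, n_iter)
    coords, stress, n_iter = best
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=list(dist.ids), columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        stress=float(stress),
        n_restarts=len(inits),
        seed=seed,
        converged=bool(n_iter < max_iter),
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int


def _permanova_ss(d2: np.ndarray, g: np.ndarray, labels) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Huygens)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(g == lab)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 4999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with a seeded permutation null.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations), so the
    attainable minimum is 1/(n_permutations + 1).
    """
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    d = np.asarray(dist.data, dtype=float)
    d2 = d**2
    n = d.shape[0]
    a = len(labels)

    def f_stat(gvec: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, gvec, labels)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    ss_total, ss_within = _permanova_ss(d2, g, labels)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if f_stat(g[rng.permutation(n)]) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), r2=float(r2), p=float(p), n_permutations=n_permutations
    )


@dataclass
class DispersionResult:
    statistic: float  # ANOVA F on distances to group spatial medians
    p: float
    group_dispersions: dict
    n_permutations: int


def _spatial_median_distances(coords: np.ndarray, neg: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Distances of group members to the group spatial median.

    ``coords`` are the positive-eigenvalue PCoA axes, ``neg`` the
    imaginary (negative-eigenvalue) axes; squared distances subtract the
    imaginary part and are clamped at zero (vegan's correction).
    """
    pos = coords[idx]
    nneg = neg[idx]

    # geometric median fitted with every axis treated as real (the sign
    # correction applies only to the reported distances, not the fit)
    def objective(m):
        mp, mn = m[: pos.shape[1]], m[pos.shape[1]:]
        d2 = ((pos - mp) ** 2).sum(axis=1) + ((nneg - mn) ** 2).sum(axis=1)
        return np.sqrt(d2).sum()

    x0 = np.concatenate([pos.mean(axis=0), nneg.mean(axis=0)])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    m = res.x
    mp, mn = m[: pos.shape[1]], m[pos.shape[1]:]
    d2 = ((pos - mp) ** 2).sum(axis=1) - ((nneg - mn) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0, None))


def dispersion_test(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Samples are embedded by principal-coordinates analysis (negative
    eigenvalues kept as imaginary axes); each sample's distance to its
    group spatial median is compared between groups by a permutation F
    test on the distances.
    """
    g = np.asarray(groups)
    labels = list(dict.fromkeys(g))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (g == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    w, v = np.linalg.eigh(G)
    tol = 1e-10 * max(1.0, np.abs(w).max())
    pos_axes = v[:, w > tol] * np.sqrt(w[w > tol])
    neg_axes = v[:, w < -tol] * np.sqrt(-w[w < -tol])
    if neg_axes.size == 0:
        neg_axes = np.zeros((n, 1))

    dists = np.empty(n)
    for lab in labels:
        idx = np.flatnonzero(g == lab)
        dists[idx] = _spatial_median_distances(pos_axes, neg_axes, idx)

    def anova_f(gvec: np.ndarray, y: np.ndarray) -> float:
        grand = y.mean()
        ss_b = sum((gvec == lab).sum() * (y[gvec == lab].mean() - grand) ** 2 for lab in labels)
        ss_w = sum(((y[gvec == lab] - y[gvec == lab].mean()) ** 2).sum() for lab in labels)
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / (len(labels) - 1)) / (ss_w / (n - len(labels)))

    f_obs = anova_f(g, dists)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if anova_f(g[rng.permutation(n)], dists) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return DispersionResult(
        statistic=float(f_obs),
        p=float(p),
        group_dispersions={lab: float(dists[g == lab].mean()) for lab in labels},
        n_permutations=n_permutations,
    )
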