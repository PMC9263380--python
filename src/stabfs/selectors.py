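"""Supervised and unsupervised feature scorers behind a uniform ranking API.

Ten scorers populate the method grid: four supervised filters (F score, T
score, ReliefF, Fisher score) and six unsupervised ones (Laplacian score,
SPEC, MCFS, NDFS, UDFS, and a mean-absolute-correlation redundancy score).
Every scorer is exposed as a scikit-learn selector estimator with ``fit`` /
``transform`` / ``get_support`` and a fitted ``scores_`` vector, oriented so
that HIGHER scores are always preferred; methods whose native criterion is
"smaller is better" (Laplacian score, SPEC variants phi1/phi2) are negated
internally.  Module-level functions wrap the estimators for one-shot scoring.

Degenerate features are handled explicitly rather than propagated as NaN/inf:
a globally constant feature scores 0 for the variance-ratio filters, a feature
with zero within-class variance but distinct class means is capped at
``SCORE_CAP``, and a constant feature gets the worst possible score for the
locality-based methods (no structure to preserve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import linalg as sla
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import lars_path
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import GraphStructureError, ParameterError
from .graph import build_affinity_graph

__all__ = [
    "SCORE_CAP",
    "LAPLACIAN_WORST",
    "SelectorSpec",
    "SELECTOR_REGISTRY",
    "get_selector_spec",
    "supervised_pool",
    "unsupervised_pool",
    "select_top_k",
    "FScoreRanker",
    "TScoreRanker",
    "ReliefFRanker",
    "FisherScoreRanker",
    "LaplacianScoreRanker",
    "SPECRanker",
    "MCFSRanker",
    "NDFSRanker",
    "UDFSRanker",
    "PearsonRedundancyRanker",
    "RandomRanker",
    "f_score",
    "t_score",
    "fisher_score",
    "relieff",
    "laplacian_score",
    "spec_score",
    "mcfs_score",
    "ndfs_score",
    "udfs_score",
    "pearson_redundancy_score",
]

#: cap for scores that are formally infinite (zero denominator, distinct means)
SCORE_CAP = 1e12

#: score assigned to constant features by the Laplacian ranker; the negated
#: Rayleigh quotient lies in [-2, 0], so -4 is strictly worse than any
#: attainable value while staying finite
LAPLACIAN_WORST = -4.0

_EPS = np.finfo(float).eps


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` largest scores; ties go to the lowest index.

    Returns a sorted integer array (ascending feature index).
    """
    scores = np.asarray(scores, dtype=float)
    d = scores.shape[0]
    if not 1 <= k <= d:
        raise ParameterError(f"k must be in [1, {d}], got {k}")
    # stable sort on the negated scores keeps the lowest index first among ties
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# score kernels (pure functions on arrays; no preprocessing)
# ---------------------------------------------------------------------------

def _class_split(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y).ravel()
    uniq = np.unique(y)
    if uniq.shape[0] != 2:
        raise ParameterError(f"binary labels required, found classes {uniq}")
    return y == uniq[0], y == uniq[1]


def _f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    m0, m1 = _class_split(y)
    X0, X1 = X[m0], X[m1]
    n0, n1 = X0.shape[0], X1.shape[0]
    n = n0 + n1
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    mu = X.mean(axis=0)
    ssb = n0 * (mu0 - mu) ** 2 + n1 * (mu1 - mu) ** 2  # df = 1
    ssw = ((X0 - mu0) ** 2).sum(axis=0) + ((X1 - mu1) ** 2).sum(axis=0)
    msw = ssw / (n - 2)
    const_within = (np.ptp(X0, axis=0) == 0) & (np.ptp(X1, axis=0) == 0)
    const_global = np.ptp(X, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(msw > 0, ssb / np.where(msw > 0, msw, 1.0), 0.0)
    out[const_within & ~const_global] = SCORE_CAP
    out[const_global] = 0.0
    return np.minimum(out, SCORE_CAP)


def _t_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    m0, m1 = _class_split(y)
    X0, X1 = X[m0], X[m1]
    n0, n1 = X0.shape[0], X1.shape[0]
    if min(n0, n1) < 2:
        raise ParameterError("each class needs at least 2 subjects for the T score")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    v0 = X0.var(axis=0, ddof=1)
    v1 = X1.var(axis=0, ddof=1)
    se = np.sqrt(v0 / n0 + v1 / n1)
    diff = np.abs(mu1 - mu0)
    out = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    out[(se == 0) & (diff > 0)] = SCORE_CAP
    return np.minimum(out, SCORE_CAP)


def _fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # between-class over within-class variance with population (ddof=0)
    # class variances: sum_c n_c (mu_c - mu)^2 / sum_c n_c sigma_c^2
    m0, m1 = _class_split(y)
    X0, X1 = X[m0], X[m1]
    n0, n1 = X0.shape[0], X1.shape[0]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    mu = X.mean(axis=0)
    num = n0 * (mu0 - mu) ** 2 + n1 * (mu1 - mu) ** 2
    den = n0 * X0.var(axis=0, ddof=0) + n1 * X1.var(axis=0, ddof=0)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out[(den == 0) & (num > 0)] = SCORE_CAP
    return np.minimum(out, SCORE_CAP)


def _relieff_scores(X: np.ndarray, y: np.ndarray, k_neighbors: int) -> np.ndarray:
    """ReliefF weights with every instance used as an anchor (no subsampling).

    Features are min-max scaled, so the per-feature difference is normalised
    by the feature range and distances are computed on the scaled table.
    """
    y = np.asarray(y).ravel()
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.shape[0] != 2:
        raise ParameterError("binary labels required")
    if counts.min() <= k_neighbors:
        raise ParameterError(
            f"each class must have more than k_neighbors={k_neighbors} subjects "
            f"(smallest class: {counts.min()})"
        )
    rng_ = np.ptp(X, axis=0)
    scale = np.where(rng_ > 0, rng_, 1.0)
    Xs = (X - X.min(axis=0)) / scale  # constant features become all-zero

    dist = squareform(pdist(Xs))
    np.fill_diagonal(dist, np.inf)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    w = np.zeros(d)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        other = np.flatnonzero(y != y[i])
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_neighbors]]
        w -= np.abs(Xs[hits] - Xs[i]).sum(axis=0)
        # binary case: the miss class weight P(c)/(1 - P(y_i)) equals 1
        other_class = classes[classes != y[i]][0]
        coef = priors[other_class] / (1.0 - priors[y[i]])
        w += coef * np.abs(Xs[misses] - Xs[i]).sum(axis=0)
    return w / (n * k_neighbors)


def _graph_degrees(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.size == 0 or W.sum() == 0:
        raise GraphStructureError("affinity graph has no edges")
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        raise GraphStructureError("graph contains isolated vertices")
    return deg


def _laplacian_scores(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Negated Laplacian score (higher = better locality preservation)."""
    deg = _graph_degrees(W)
    L = np.diag(deg) - W
    # degree-weighted mean centering
    Ft = X - (deg @ X) / deg.sum()
    num = np.einsum("if,if->f", Ft, L @ Ft)
    den = np.einsum("if,if->f", Ft, deg[:, None] * Ft)
    tiny = _EPS * max(1.0, float(den.max(initial=0.0)))
    out = np.where(den > tiny, -(num / np.where(den > tiny, den, 1.0)), LAPLACIAN_WORST)
    return out


def _spec_scores(X: np.ndarray, W: np.ndarray, variant: str = "phi2",
                 spec_k: int = 5) -> np.ndarray:
    """Spectral feature scoring on the normalised graph Laplacian.

    ``phi1``: Rayleigh quotient of the weighted feature (negated).  ``phi2``
    (default): phi1 with the trivial-eigenvector component removed (negated).
    ``phi3``: alignment with the ``spec_k`` smallest non-trivial eigenpairs,
    weighted by (2 - lambda); higher is better natively.
    """
    deg = _graph_degrees(W)
    dhalf = np.sqrt(deg)
    nL = np.eye(W.shape[0]) - W / np.outer(dhalf, dhalf)
    xi0 = dhalf / np.linalg.norm(dhalf)

    F = dhalf[:, None] * X
    norms = np.linalg.norm(F, axis=0)
    ok = norms > 0
    Fh = np.where(ok, F / np.where(ok, norms, 1.0), 0.0)

    if variant == "phi3":
        vals, vecs = np.linalg.eigh(nL)
        k_use = min(spec_k, vals.shape[0] - 1)
        lam = vals[1: 1 + k_use]
        align = vecs[:, 1: 1 + k_use].T @ Fh  # (k_use, d)
        out = ((2.0 - lam)[:, None] * align**2).sum(axis=0)
        out[~ok] = -SCORE_CAP
        return out

    phi1 = np.einsum("if,if->f", Fh, nL @ Fh)
    if variant == "phi1":
        out = -phi1
        out[~ok] = -SCORE_CAP
        return out
    if variant != "phi2":
        raise ParameterError(f"unknown SPEC variant {variant!r}")
    trivial = (xi0 @ Fh) ** 2
    resid = 1.0 - trivial
    degenerate = (resid <= 1e-10) | ~ok  # constant features align fully with xi0
    out = np.where(degenerate, -SCORE_CAP,
                   -(phi1 / np.where(degenerate, 1.0, resid)))
    return out


def _mcfs_scores(X: np.ndarray, W: np.ndarray, n_clusters: int,
                 n_select_hint: int) -> np.ndarray:
    """Multi-cluster feature selection: spectral embedding + L1 regressions."""
    n, d = X.shape
    if not 2 <= n_clusters < n:
        raise ParameterError(f"n_clusters must be in [2, {n - 1}]")
    deg = _graph_degrees(W)
    L = np.diag(deg) - W
    try:
        vals, vecs = sla.eigh(L, np.diag(deg))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate graph
        raise GraphStructureError(f"spectral embedding failed: {exc}") from exc
    k_eig = n_clusters - 1
    embedding = vecs[:, 1: 1 + k_eig]  # skip the trivial eigenvector

    hint = int(min(max(n_select_hint, 1), d))
    scores = np.zeros(d)
    for j in range(embedding.shape[1]):
        _, _, coefs = lars_path(X, embedding[:, j], method="lasso",
                                max_iter=hint)
        scores = np.maximum(scores, np.abs(coefs[:, -1]))
    return scores


def _row_norms(M: np.ndarray) -> np.ndarray:
    return np.sqrt((M**2).sum(axis=1))


def _ndfs_scores(X: np.ndarray, W: np.ndarray, n_clusters: int, alpha: float,
                 beta: float, gamma: float, max_iter: int, tol: float,
                 random_state: int) -> tuple[np.ndarray, bool, list[float]]:
    """Non-negative discriminative feature selection by multiplicative updates.

    Minimises  Tr(F'LF) + alpha*(||XWm - F||^2 + beta*||Wm||_{2,1})
    + gamma/2*||F'F - I||^2  over nonnegative pseudo cluster indicators F and
    the feature mapping Wm; the feature score is the l2 row norm of Wm.  F is
    initialised from a seeded k-means clustering of the graph's spectral
    embedding (shifted to stay strictly positive), which anchors the
    multiplicative updates near a meaningful partition.
    """
    n, d = X.shape
    if min(alpha, beta, gamma) <= 0:
        raise ParameterError("alpha, beta and gamma must be > 0")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    deg = _graph_degrees(W)
    L = np.diag(deg) - W
    Lp = np.clip(L, 0.0, None)
    Ln = np.clip(-L, 0.0, None)

    try:
        _, vecs = sla.eigh(L, np.diag(deg))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate graph
        raise GraphStructureError(f"spectral embedding failed: {exc}") from exc
    embedding = vecs[:, :n_clusters]
    km = KMeans(n_clusters=n_clusters, n_init=10,
                random_state=int(random_state) % (2**31)).fit(embedding)
    F = np.eye(n_clusters)[km.labels_] + 0.2
    XtX = X.T @ X
    D_w = np.ones(d)
    eps = 1e-12
    Ic = np.eye(n_clusters)

    def objective(F, Wm):
        fit = X @ Wm - F
        return float(
            np.einsum("if,if->", F, L @ F)
            + alpha * ((fit**2).sum() + beta * _row_norms(Wm).sum())
            + 0.5 * gamma * ((F.T @ F - Ic) ** 2).sum()
        )

    history: list[float] = []
    converged = False
    Wm = np.zeros((d, n_clusters))
    for _ in range(max_iter):
        Wm = np.linalg.solve(XtX + beta * np.diag(D_w), X.T @ F)
        history.append(objective(F, Wm))

        XW = X @ Wm
        XWp = np.clip(XW, 0.0, None)
        XWn = np.clip(-XW, 0.0, None)
        numer = Ln @ F + alpha * XWp + gamma * F
        denom = Lp @ F + alpha * (F + XWn) + gamma * F @ (F.T @ F) + eps
        F = np.maximum(F * np.sqrt(numer / denom), eps)

        D_w = 1.0 / (2.0 * _row_norms(Wm) + eps)
        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if abs(prev - cur) / max(abs(prev), 1.0) < tol:
                converged = True
                break
    Wm = np.linalg.solve(XtX + beta * np.diag(D_w), X.T @ F)
    history.append(objective(F, Wm))
    if not converged:
        warnings.warn("NDFS did not converge within max_iter", RuntimeWarning)
    return _row_norms(Wm), converged, history


def _udfs_scores(X: np.ndarray, n_clusters: int, gamma: float,
                 k_neighbors: int, max_iter: int, tol: float,
                 local_reg: float = 1.0) -> tuple[np.ndarray, bool, list[float]]:
    """l2,1-regularised local discriminative analysis (UDFS).

    Builds the local-scatter matrix M from each sample's (k+1)-point
    neighbourhood and solves  min Tr(W'MW) + gamma*||W||_{2,1}  s.t. W'W = I
    by iteratively reweighted eigendecomposition.  Constant features carry no
    local discriminative information and are excluded with score 0.
    """
    n, d_full = X.shape
    if min(gamma, tol) <= 0 or max_iter < 1:
        raise ParameterError("gamma and tol must be > 0 and max_iter >= 1")
    if not 1 <= k_neighbors < n:
        raise ParameterError(f"k_neighbors must be in [1, {n - 1}]")

    active = np.ptp(X, axis=0) > 0
    Xa = X[:, active]
    d = Xa.shape[1]
    scores = np.zeros(d_full)
    if d == 0:
        return scores, True, []

    dist = squareform(pdist(Xa))
    np.fill_diagonal(dist, -1.0)  # self is always the first neighbour
    order = np.argsort(dist, axis=1, kind="stable")
    k1 = k_neighbors + 1
    H = np.eye(k1) - np.ones((k1, k1)) / k1

    S = np.zeros((n, n))
    for i in range(n):
        idx = order[i, :k1]
        Xi = Xa[idx]  # (k+1) x d local block
        G = H @ Xi @ Xi.T @ H
        B = np.linalg.inv(G + local_reg * np.eye(k1))
        S[np.ix_(idx, idx)] += H @ B @ H
    A = Xa.T @ S @ Xa
    A = local_reg * 0.5 * (A + A.T)

    c = min(n_clusters, d)
    Dw = np.ones(d)
    eps = 1e-12
    history: list[float] = []
    converged = False
    Wm = np.zeros((d, c))
    for _ in range(max_iter):
        P = A + gamma * np.diag(Dw)
        _, vecs = np.linalg.eigh(0.5 * (P + P.T))
        Wm = vecs[:, :c]
        history.append(float(np.einsum("ic,ic->", Wm, A @ Wm)
                             + gamma * _row_norms(Wm).sum()))
        Dw = 1.0 / (2.0 * _row_norms(Wm) + eps)
        if len(history) >= 2:
            prev, cur = history[-2], history[-1]
            if abs(prev - cur) / max(abs(prev), 1.0) < tol:
                converged = True
                break
    if not converged:
        warnings.warn("UDFS did not converge within max_iter", RuntimeWarning)
    scores[active] = _row_norms(Wm)
    return scores, converged, history


def _pearson_redundancy_scores(X: np.ndarray) -> np.ndarray:
    """Negated mean absolute pairwise correlation (higher = less redundant)."""
    n, d = X.shape
    if d < 2:
        raise ParameterError("redundancy scoring needs at least 2 features")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s): correlations treated as 0",
            RuntimeWarning,
        )
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    Xn = np.where(sd > 0, Xc / np.where(sd > 0, sd, 1.0), 0.0)
    R = (Xn.T @ Xn) / n
    np.fill_diagonal(R, 0.0)
    return -np.abs(R).sum(axis=1) / (d - 1)


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class _BaseRanker(SelectorMixin, BaseEstimator):
    """Shared top-k selection logic; subclasses implement ``_score``."""

    def __init__(self, k=None):
        self.k = k

    requires_labels: bool = False

    def fit(self, X, y=None):
        if self.requires_labels:
            X, y = validate_data(self, X, y)
        else:
            X = validate_data(self, X)
        self.scores_ = self._score(np.asarray(X, dtype=float),
                                   None if y is None else np.asarray(y))
        if not np.all(np.isfinite(self.scores_)):
            raise RuntimeError("internal error: non-finite selector scores")
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "scores_")
        d = self.scores_.shape[0]
        k = d if self.k is None else int(self.k)
        mask = np.zeros(d, dtype=bool)
        mask[select_top_k(self.scores_, k)] = True
        return mask

    def top_k_indices(self) -> np.ndarray:
        return np.flatnonzero(self._get_support_mask())


class FScoreRanker(_BaseRanker):
    """One-way ANOVA F statistic per feature (supervised filter)."""

    requires_labels = True

    def _score(self, X, y):
        return _f_scores(X, y)


class TScoreRanker(_BaseRanker):
    """Absolute Welch t statistic per feature (supervised filter)."""

    requires_labels = True

    def _score(self, X, y):
        return _t_scores(X, y)


class FisherScoreRanker(_BaseRanker):
    """Fisher criterion: between-class over summed within-class variance."""

    requires_labels = True

    def _score(self, X, y):
        return _fisher_scores(X, y)


class ReliefFRanker(_BaseRanker):
    """ReliefF nearest hit/miss weighting, all instances as anchors."""

    requires_labels = True

    def __init__(self, k=None, n_neighbors=5):
        super().__init__(k=k)
        self.n_neighbors = n_neighbors

    def _score(self, X, y):
        return _relieff_scores(X, y, self.n_neighbors)


class _GraphRanker(_BaseRanker):
    """Unsupervised ranker operating on a sample affinity graph.

    Features are z-scored before graph construction so that no single raw
    scale dominates the Euclidean geometry; a precomputed ``affinity`` matrix
    bypasses both standardisation and graph building.
    """

    def __init__(self, k=None, n_neighbors=5, kernel_width="auto",
                 affinity=None):
        super().__init__(k=k)
        self.n_neighbors = n_neighbors
        self.kernel_width = kernel_width
        self.affinity = affinity

    def _prepare(self, X):
        if self.affinity is not None:
            return X, np.asarray(self.affinity, dtype=float)
        sd = X.std(axis=0)
        Xs = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        k = min(self.n_neighbors, X.shape[0] - 1)
        return Xs, build_affinity_graph(Xs, k_neighbors=k,
                                        kernel_width=self.kernel_width)


class LaplacianScoreRanker(_GraphRanker):
    """Laplacian score (negated: higher = better locality preservation)."""

    def _score(self, X, y=None):
        Xs, W = self._prepare(X)
        return _laplacian_scores(Xs, W)


class SPECRanker(_GraphRanker):
    """Spectral feature selection on the normalised graph Laplacian."""

    def __init__(self, k=None, n_neighbors=5, kernel_width="auto",
                 affinity=None, variant="phi2", spec_k=5):
        super().__init__(k=k, n_neighbors=n_neighbors,
                         kernel_width=kernel_width, affinity=affinity)
        self.variant = variant
        self.spec_k = spec_k

    def _score(self, X, y=None):
        Xs, W = self._prepare(X)
        return _spec_scores(Xs, W, variant=self.variant, spec_k=self.spec_k)


class MCFSRanker(_GraphRanker):
    """Multi-cluster feature selection (spectral embedding + LARS lasso)."""

    def __init__(self, k=None, n_neighbors=5, kernel_width="auto",
                 affinity=None, n_clusters=2, n_select_hint=None):
        super().__init__(k=k, n_neighbors=n_neighbors,
                         kernel_width=kernel_width, affinity=affinity)
        self.n_clusters = n_clusters
        self.n_select_hint = n_select_hint

    def _score(self, X, y=None):
        Xs, W = self._prepare(X)
        hint = self.n_select_hint
        if hint is None:
            hint = self.k if self.k is not None else X.shape[1]
        return _mcfs_scores(Xs, W, self.n_clusters, hint)


class NDFSRanker(_GraphRanker):
    """Non-negative discriminative feature selection (multiplicative updates).

    Fitted attributes beyond ``scores_``: ``converged_`` and
    ``objective_history_`` (one value per iteration, non-increasing).
    """

    def __init__(self, k=None, n_neighbors=5, kernel_width="auto",
                 affinity=None, n_clusters=2, alpha=1.0, beta=1.0, gamma=1e8,
                 max_iter=100, tol=1e-6, random_state=0):
        super().__init__(k=k, n_neighbors=n_neighbors,
                         kernel_width=kernel_width, affinity=affinity)
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _score(self, X, y=None):
        Xs, W = self._prepare(X)
        scores, self.converged_, self.objective_history_ = _ndfs_scores(
            Xs, W, self.n_clusters, self.alpha, self.beta, self.gamma,
            self.max_iter, self.tol, self.random_state,
        )
        return scores


class UDFSRanker(_BaseRanker):
    """l2,1-regularised local discriminative feature selection."""

    def __init__(self, k=None, n_clusters=2, gamma=0.1, n_neighbors=5,
                 max_iter=100, tol=1e-6, local_reg=1.0):
        super().__init__(k=k)
        self.n_clusters = n_clusters
        self.gamma = gamma
        self.n_neighbors = n_neighbors
        self.max_iter = max_iter
        self.tol = tol
        self.local_reg = local_reg

    def _score(self, X, y=None):
        sd = X.std(axis=0)
        Xs = np.where(sd > 0, (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        k = min(self.n_neighbors, X.shape[0] - 1)
        scores, self.converged_, self.objective_history_ = _udfs_scores(
            Xs, self.n_clusters, self.gamma, k, self.max_iter, self.tol,
            local_reg=self.local_reg,
        )
        return scores


class PearsonRedundancyRanker(_BaseRanker):
    """Redundancy filter: negated mean absolute pairwise correlation."""

    def _score(self, X, y=None):
        return _pearson_redundancy_scores(X)


class RandomRanker(_BaseRanker):
    """Seeded uniform-random scores: a null baseline for the decision graph."""

    def __init__(self, k=None, random_state=0):
        super().__init__(k=k)
        self.random_state = random_state

    def _score(self, X, y=None):
        rng = np.random.default_rng(self.random_state)
        return rng.uniform(size=X.shape[1])


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectorSpec:
    """Identity and hyperparameters of one scorer in the method pool."""

    id: str
    name: str
    kind: str  # "supervised" | "unsupervised"
    factory: type
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    seeded: bool = False

    def build(self, k: int | None = None, seed: int | None = None,
              **overrides) -> _BaseRanker:
        """Instantiate the ranker keeping ``k`` features (None = all)."""
        params = dict(self.hyperparameters)
        params.update(overrides)
        if self.seeded and seed is not None:
            params["random_state"] = int(seed)
        return self.factory(k=k, **params)


SELECTOR_REGISTRY: dict[str, SelectorSpec] = {
    "S1": SelectorSpec("S1", "F score", "supervised", FScoreRanker),
    "S2": SelectorSpec("S2", "T score", "supervised", TScoreRanker),
    "S3": SelectorSpec("S3", "ReliefF", "supervised", ReliefFRanker),
    "S4": SelectorSpec("S4", "Fisher score", "supervised", FisherScoreRanker),
    "U1": SelectorSpec("U1", "Laplacian score", "unsupervised", LaplacianScoreRanker),
    "U2": SelectorSpec("U2", "SPEC", "unsupervised", SPECRanker),
    "U3": SelectorSpec("U3", "MCFS", "unsupervised", MCFSRanker),
    "U4": SelectorSpec("U4", "NDFS", "unsupervised", NDFSRanker, seeded=True),
    "U5": SelectorSpec("U5", "UDFS", "unsupervised", UDFSRanker),
    "U6": SelectorSpec("U6", "Pearson score", "unsupervised", PearsonRedundancyRanker),
    # null baselines (not part of the default pools)
    "S0": SelectorSpec("S0", "Random (supervised slot)", "supervised",
                       RandomRanker, seeded=True),
    "U0": SelectorSpec("U0", "Random (unsupervised slot)", "unsupervised",
                       RandomRanker, seeded=True),
}

_NAME_INDEX = {spec.name.lower(): spec.id for spec in SELECTOR_REGISTRY.values()}


def get_selector_spec(id_or_name: str) -> SelectorSpec:
    key = id_or_name.strip()
    if key.upper() in SELECTOR_REGISTRY:
        return SELECTOR_REGISTRY[key.upper()]
    if key.lower() in _NAME_INDEX:
        return SELECTOR_REGISTRY[_NAME_INDEX[key.lower()]]
    raise ParameterError(f"unknown selector {id_or_name!r}")


def supervised_pool() -> list[SelectorSpec]:
    return [SELECTOR_REGISTRY[i] for i in ("S1", "S2", "S3", "S4")]


def unsupervised_pool() -> list[SelectorSpec]:
    return [SELECTOR_REGISTRY[i] for i in ("U1", "U2", "U3", "U4", "U5", "U6")]


# ---------------------------------------------------------------------------
# one-shot functional wrappers (kernels on explicit inputs, no preprocessing)
# ---------------------------------------------------------------------------

def f_score(X, y) -> np.ndarray:
    return _f_scores(np.asarray(X, dtype=float), np.asarray(y))


def t_score(X, y) -> np.ndarray:
    return _t_scores(np.asarray(X, dtype=float), np.asarray(y))


def fisher_score(X, y) -> np.ndarray:
    return _fisher_scores(np.asarray(X, dtype=float), np.asarray(y))


def relieff(X, y, k_neighbors: int = 5) -> np.ndarray:
    return _relieff_scores(np.asarray(X, dtype=float), np.asarray(y), k_neighbors)


def laplacian_score(X, graph) -> np.ndarray:
    return _laplacian_scores(np.asarray(X, dtype=float), np.asarray(graph, dtype=float))


def spec_score(X, graph, variant: str = "phi2", spec_k: int = 5) -> np.ndarray:
    return _spec_scores(np.asarray(X, dtype=float),
                        np.asarray(graph, dtype=float), variant, spec_k)


def mcfs_score(X, graph, n_clusters: int = 2,
               n_select_hint: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    hint = X.shape[1] if n_select_hint is None else n_select_hint
    return _mcfs_scores(X, np.asarray(graph, dtype=float), n_clusters, hint)


def ndfs_score(X, graph, n_clusters: int = 2, alpha: float = 1.0,
               beta: float = 1.0, gamma: float = 1e8, max_iter: int = 100,
               tol: float = 1e-6, seed: int = 0) -> np.ndarray:
    scores, _, _ = _ndfs_scores(np.asarray(X, dtype=float),
                                np.asarray(graph, dtype=float), n_clusters,
                                alpha, beta, gamma, max_iter, tol, seed)
    return scores


def udfs_score(X, n_clusters: int = 2, gamma: float = 0.1,
               k_neighbors: int = 5, max_iter: int = 100,
               tol: float = 1e-6) -> np.ndarray:
    scores, _, _ = _udfs_scores(np.asarray(X, dtype=float), n_clusters, gamma,
                                k_neighbors, max_iter, tol)
    return scores


def pearson_redundancy_score(X) -> np.ndarray:
    return _pearson_redundancy_scores(np.asarray(X, dtype=float))
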