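"""PLS-correlation between the receptor atlas and a paired regional matrix.

The cross-covariance of the two z-scored blocks, X'Y/(n-1), is decomposed
by SVD into paired latent variables maximizing covariance. Each latent
variable carries orthonormal receptor and term weights and a singular
value whose squared share of the total is the covariance explained.
Region scores are data projections onto the weights; loadings are the
Pearson correlations between original features and scores. Latent-
variable significance is assessed on the singular value against spins of
the receptor block; generalizability by distance-dependent
cross-validation of the train/test score correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import ParcelGeometry
from .nulls import SpinEnsemble, spin_pvalue
from .multilinear import CVResult, _cv_folds, _safe_corr

__all__ = [
    "PLSCorrelation",
    "PLSResult",
    "pls_decompose",
    "pls_significance",
    "pls_loadings",
    "pls_distance_cv",
]


@dataclass
class PLSResult:
    """Latent variables of a PLS-correlation decomposition."""

    x_weights: np.ndarray  # (p, n_lv), orthonormal columns
    y_weights: np.ndarray  # (t, n_lv), orthonormal columns
    singular_values: np.ndarray
    cov_explained: np.ndarray  # s^2 / sum(s^2), non-increasing
    x_scores: np.ndarray  # (n, n_lv)
    y_scores: np.ndarray
    x_loadings: np.ndarray  # feature-score Pearson r, (p, n_lv)
    y_loadings: np.ndarray
    p_spin: np.ndarray | None = None


def pls_loadings(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each data column with each score vector."""
    data = np.asarray(data, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != data.shape[0]:
        scores = scores.T
    dc = data - data.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    dsd = dc.std(axis=0)
    ssd = sc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        load = (dc.T @ sc) / data.shape[0] / np.outer(dsd, ssd)
    return load  # NaN flags zero-variance columns


class PLSCorrelation(BaseEstimator):
    """PLS-correlation (SVD of the cross-covariance) of two regional blocks.

    Parameters
    ----------
    n_components : int or None
        Latent variables to retain; default keeps all.

    Fitted attributes mirror :class:`PLSResult` with trailing underscores
    (``x_weights_``, ``singular_values_``, ``cov_explained_``, ...).
    The sign of each latent variable is fixed so that its receptor score
    vector correlates positively with the regional mean receptor density.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PLSCorrelation":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n = X.shape[0]
        if Y.shape[0] != n:
            raise ValueError("X and Y must have the same number of regions")
        C = X.T @ Y / (n - 1)
        if np.allclose(C, 0, atol=1e-14):
            raise ValueError("cross-covariance matrix is numerically zero")
        u, s, vt = np.linalg.svd(C, full_matrices=False)
        k = self.n_components or len(s)
        u, s, v = u[:, :k], s[:k], vt[:k].T

        x_scores = X @ u
        mean_map = X.mean(axis=1)
        for j in range(u.shape[1]):
            r = _safe_corr(x_scores[:, j], mean_map)
            if r < 0:
                u[:, j] = -u[:, j]
                v[:, j] = -v[:, j]
        x_scores = X @ u
        y_scores = Y @ v

        self.x_weights_ = u
        self.y_weights_ = v
        self.singular_values_ = s
        self.cov_explained_ = s**2 / np.sum(s**2)
        self.x_scores_ = x_scores
        self.y_scores_ = y_scores
        self.x_loadings_ = pls_loadings(X, x_scores)
        self.y_loadings_ = pls_loadings(Y, y_scores)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(
        self, X: np.ndarray, Y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        return X @ self.x_weights_, Y @ self.y_weights_

    def result(self, p_spin: np.ndarray | None = None) -> PLSResult:
        return PLSResult(
            x_weights=self.x_weights_,
            y_weights=self.y_weights_,
            singular_values=self.singular_values_,
            cov_explained=self.cov_explained_,
            x_scores=self.x_scores_,
            y_scores=self.y_scores_,
            x_loadings=self.x_loadings_,
            y_loadings=self.y_loadings_,
            p_spin=p_spin,
        )


def pls_decompose(X: np.ndarray, Y: np.ndarray) -> PLSResult:
    """SVD of the cross-covariance X'Y/(n-1) into paired latent variables."""
    return PLSCorrelation().fit(X, Y).result()


def pls_significance(
    X: np.ndarray, Y: np.ndarray, spins: SpinEnsemble
) -> np.ndarray:
    """One-sided spin p-value per latent variable, assessed on singular values.

    The receptor block's rows are spun (rotation-based reassignment), the
    cross-covariance re-decomposed, and each observed singular value
    compared to its null distribution. No Procrustes alignment is applied.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    obs = np.linalg.svd(X.T @ Y / (n - 1), compute_uv=False)
    null = np.empty((spins.n_perm, len(obs)))
    for p in range(spins.n_perm):
        Xs = X[spins.assignments[p]]
        null[p] = np.linalg.svd(Xs.T @ Y / (n - 1), compute_uv=False)
    return np.array(
        [spin_pvalue(obs[j], null[:, j], tail="one_greater") for j in range(len(obs))]
    )


def _lv1_score_corr(
    Xtr: np.ndarray, Ytr: np.ndarray, Xte: np.ndarray, Yte: np.ndarray
) -> tuple[float, float]:
    """Train/test correlation of LV1 receptor and term scores.

    The decomposition is computed on the training rows (centered by train
    means); test rows are centered by the train means and projected onto
    the train weights.
    """
    mx, my = Xtr.mean(axis=0), Ytr.mean(axis=0)
    Xtr_c, Ytr_c = Xtr - mx, Ytr - my
    C = Xtr_c.T @ Ytr_c / (Xtr.shape[0] - 1)
    u, _, vt = np.linalg.svd(C, full_matrices=False)
    u1, v1 = u[:, 0], vt[0]
    tr = _safe_corr(Xtr_c @ u1, Ytr_c @ v1)
    te = _safe_corr((Xte - mx) @ u1, (Yte - my) @ v1)
    return tr, te


def pls_distance_cv(
    X: np.ndarray,
    Y: np.ndarray,
    geometry: ParcelGeometry,
    train_frac: float = 0.75,
    spins: SpinEnsemble | None = None,
) -> CVResult:
    """Distance-dependent cross-validation of the LV1 score correlation.

    One fold per source region (75% nearest regions train, the rest test).
    Per fold the PLS decomposition is fit on the training rows and the
    correlation between receptor and term scores is recorded separately in
    the training and test sets. If a spin ensemble is given, the mean test
    correlation is compared one-sided against the same cross-validation
    run on spun receptor rows.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    folds = list(_cv_folds(geometry, train_frac))
    n = geometry.n_regions
    train_r = np.empty(n)
    test_r = np.empty(n)
    for f, (tr, te) in enumerate(folds):
        train_r[f], test_r[f] = _lv1_score_corr(X[tr], Y[tr], X[te], Y[te])
    mean_test_r = float(test_r.mean())
    p_null = None
    if spins is not None:
        null_means = np.empty(spins.n_perm)
        for p in range(spins.n_perm):
            Xs = X[spins.assignments[p]]
            vals = [
                _lv1_score_corr(Xs[tr], Y[tr], Xs[te], Y[te])[1] for tr, te in folds
            ]
            null_means[p] = float(np.mean(vals))
        p_null = spin_pvalue(mean_test_r, null_means, tail="one_greater")
    return CVResult(
        train_r=train_r, test_r=test_r, mean_test_r=mean_test_r, p_null=p_null
    )
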