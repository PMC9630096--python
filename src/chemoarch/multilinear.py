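"""Multilinear maps-from-receptors models, dominance analysis and distance CV.

A regional target map (band power, cortical-abnormality effect size, ...)
is predicted from the receptor density matrix by ordinary least squares
with intercept. Model significance is assessed against spin-permuted
targets (one-sided on adjusted R^2, batch FDR across maps). Predictor
importance uses full-subset dominance analysis: the R^2 of all 2^p - 1
submodels is enumerated from precomputed cross-products, and each
predictor's total dominance is the average (over subset sizes, then over
subsets) of its incremental R^2; total dominances sum exactly to the full
model's R^2. Generalizability uses distance-dependent cross-validation:
each region serves once as a source node whose 75% nearest regions train
the model and the remaining 25% test it, limiting spatial leakage.

Estimator classes follow scikit-learn conventions (``fit``, ``predict``,
``get_params``; fitted attributes end in an underscore); the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .geometry import ParcelGeometry
from .nulls import SpinEnsemble, spin_pvalue, fdr_correct

__all__ = [
    "MultilinearModel",
    "DominanceAnalysis",
    "MultilinearResult",
    "DominanceResult",
    "CVResult",
    "fit_multilinear",
    "spin_model_significance",
    "spin_significance_batch",
    "dominance",
    "distance_cv",
]


@dataclass
class MultilinearResult:
    """OLS fit of a regional map on the receptor matrix."""

    coefficients: np.ndarray  # per receptor
    intercept: float
    r2: float
    r2_adj: float
    p_spin: float | None = None


@dataclass
class DominanceResult:
    """Full-subset dominance decomposition of a multilinear fit.

    ``total_dominance`` partitions the full model's R^2 across predictors;
    ``percent`` normalizes by R^2 (sums to 100) and ``percent_adj`` by the
    adjusted R^2 (the convention used when comparing contributions across
    models of different fit).
    """

    total_dominance: np.ndarray
    percent: np.ndarray
    percent_adj: np.ndarray
    r2_full: float
    r2_adj_full: float
    class_aggregates: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if not np.isclose(self.total_dominance.sum(), self.r2_full, atol=1e-8):
            raise AssertionError(
                "dominance sum identity violated: "
                f"{self.total_dominance.sum():.12f} != {self.r2_full:.12f}"
            )


@dataclass
class CVResult:
    """Distance-dependent cross-validation: one fold per source region."""

    train_r: np.ndarray
    test_r: np.ndarray
    mean_test_r: float
    p_null: float | None = None


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _check_rank(X: np.ndarray, names=None) -> None:
    Xd = _design(X)
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # identify offending columns via QR pivoting on the centered matrix
        _, r = np.linalg.qr(Xd)
        small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        idx = [i - 1 for i in np.flatnonzero(small) if i > 0]
        labels = [names[i] if names else str(i) for i in idx]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {labels}")


class MultilinearModel(BaseEstimator, RegressorMixin):
    """Ordinary least squares with intercept for regional maps.

    Fitted attributes: ``coef_``, ``intercept_``, ``r2_``, ``r2_adj_``.
    Adjusted R^2 uses 1 - (1 - R^2)(n - 1)/(n - p - 1).
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MultilinearModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(f"need n_regions > n_predictors + 1 (n={n}, p={p})")
        if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
            raise ValueError("non-finite values in X or y")
        _check_rank(X)
        Xd = _design(X)
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError("target map has zero variance")
        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.r2_ = 1.0 - float((resid**2).sum()) / ss_tot
        self.r2_adj_ = 1.0 - (1.0 - self.r2_) * (n - 1) / (n - p - 1)
        self.n_features_in_ = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def fit_multilinear(X: np.ndarray, y: np.ndarray) -> MultilinearResult:
    """OLS with intercept of a regional map on receptor densities."""
    model = MultilinearModel().fit(X, y)
    return MultilinearResult(
        coefficients=model.coef_,
        intercept=model.intercept_,
        r2=model.r2_,
        r2_adj=model.r2_adj_,
    )


def _null_r2_adj(X: np.ndarray, y: np.ndarray, spins: SpinEnsemble) -> np.ndarray:
    """Adjusted R^2 of the model refit on each spun target, vectorized."""
    n, p = X.shape
    Xd = _design(X)
    pinv = np.linalg.pinv(Xd)
    Y = y[spins.assignments].T  # (n, n_perm)
    resid = Y - Xd @ (pinv @ Y)
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def spin_model_significance(
    X: np.ndarray, y: np.ndarray, spins: SpinEnsemble
) -> float:
    """One-sided spin p-value for a multilinear model's adjusted R^2.

    The target map is spun (spatial-autocorrelation-preserving rotation),
    the model refit, and the observed adjusted R^2 compared to the null
    distribution.
    """
    if spins.n_perm < 1:
        raise ValueError("spin ensemble is empty")
    observed = MultilinearModel().fit(X, y).r2_adj_
    nulls = _null_r2_adj(X, np.asarray(y, float).ravel(), spins)
    return spin_pvalue(observed, nulls, tail="one_greater")


def spin_significance_batch(
    X: np.ndarray,
    targets: np.ndarray,
    spins: SpinEnsemble,
    q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spin significance for several target maps with BH-FDR across maps.

    ``targets`` has shape (n_regions, n_maps). Returns
    ``(p_spin, significant, p_fdr)``.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[0] != X.shape[0]:
        targets = targets.T
    ps = np.array(
        [spin_model_significance(X, targets[:, j], spins) for j in range(targets.shape[1])]
    )
    rejected, p_fdr = fdr_correct(ps, q=q)
    return ps, rejected, p_fdr


# ---------------------------------------------------------------------------
# Dominance analysis
# ---------------------------------------------------------------------------


def _all_subset_r2(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R^2 of every predictor subset, indexed by bitmask (length 2^p).

    Subset fits reuse a single (p, p) cross-product matrix of the centered
    data; subsets of equal size are solved in one batched call.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    p = X.shape[1]
    G = Xc.T @ Xc
    c = Xc.T @ yc
    ss_tot = float(yc @ yc)
    r2 = np.zeros(1 << p)
    cols = np.arange(p)
    for k in range(1, p + 1):
        idx = np.array(list(combinations(cols, k)), dtype=np.intp)  # (m, k)
        Gs = G[idx[:, :, None], idx[:, None, :]]  # (m, k, k)
        cs = c[idx]  # (m, k)
        beta = np.linalg.solve(Gs, cs[..., None])[..., 0]
        expl = np.einsum("mk,mk->m", beta, cs)
        masks = (1 << idx).sum(axis=1)
        r2[masks] = expl / ss_tot
    return r2


def _total_dominance(r2: np.ndarray, p: int) -> np.ndarray:
    """Average incremental R^2 per predictor: mean over subset sizes of the
    mean increment across same-size subsets not containing the predictor."""
    masks = np.arange(1 << p, dtype=np.int64)
    sizes = np.bitwise_count(masks).astype(np.intp)
    total = np.empty(p)
    for i in range(p):
        bit = 1 << i
        without = masks[(masks & bit) == 0]
        inc = r2[without | bit] - r2[without]
        k = sizes[(masks & bit) == 0]
        sums = np.bincount(k, weights=inc, minlength=p)
        counts = np.bincount(k, minlength=p)
        level_means = sums[:p] / counts[:p]  # sizes 0 .. p-1
        total[i] = level_means.mean()
    return total


class DominanceAnalysis(BaseEstimator):
    """Full-subset dominance analysis of a multilinear regression.

    Parameters
    ----------
    max_predictors : int
        Guard on full enumeration (2^p - 1 submodels); raise beyond it.
    classes : dict, optional
        Mapping class label -> list of predictor indices for aggregated
        (mean percent) contributions per receptor class.

    Fitted attributes: ``total_dominance_``, ``percent_``,
    ``percent_adj_``, ``r2_full_``, ``r2_adj_full_``.
    """

    def __init__(self, max_predictors: int = 20, classes: dict | None = None):
        self.max_predictors = max_predictors
        self.classes = classes

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DominanceAnalysis":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if p > self.max_predictors:
            raise ValueError(
                f"p={p} exceeds the full-enumeration guard "
                f"({self.max_predictors}); select a predictor subset first"
            )
        full = MultilinearModel().fit(X, y)
        r2 = _all_subset_r2(X, y)
        total = _total_dominance(r2, p)
        self.total_dominance_ = total
        self.r2_full_ = full.r2_
        self.r2_adj_full_ = full.r2_adj_
        self.percent_ = 100.0 * total / full.r2_
        self.percent_adj_ = 100.0 * total / full.r2_adj_
        return self

    def result(self) -> DominanceResult:
        agg = None
        if self.classes is not None:
            agg = {
                label: float(np.mean(self.percent_[list(idx)]))
                for label, idx in self.classes.items()
            }
        return DominanceResult(
            total_dominance=self.total_dominance_,
            percent=self.percent_,
            percent_adj=self.percent_adj_,
            r2_full=self.r2_full_,
            r2_adj_full=self.r2_adj_full_,
            class_aggregates=agg,
        )


def dominance(
    X: np.ndarray,
    y: np.ndarray,
    classes: dict | None = None,
    max_predictors: int = 20,
) -> DominanceResult:
    """Full-subset dominance decomposition of the fit of y on X."""
    return DominanceAnalysis(max_predictors=max_predictors, classes=classes).fit(
        X, y
    ).result()


# ---------------------------------------------------------------------------
# Distance-dependent cross-validation
# ---------------------------------------------------------------------------


def _cv_folds(geometry: ParcelGeometry, train_frac: float):
    """Yield (train_idx, test_idx) with each region once as source node."""
    n = geometry.n_regions
    n_train = ceil(train_frac * n)
    if n - n_train < 3:
        raise ValueError("test set smaller than 3 regions; lower train_frac")
    for source in range(n):
        order = np.argsort(geometry.distance[source], kind="stable")
        yield order[:n_train], order[n_train:]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def distance_cv(
    X: np.ndarray,
    y: np.ndarray,
    geometry: ParcelGeometry,
    train_frac: float = 0.75,
    spins: SpinEnsemble | None = None,
) -> CVResult:
    """Distance-dependent cross-validation of a multilinear model.

    Each region serves once as a source node: the ``train_frac`` nearest
    regions (source included) form the training set, the remainder the
    test set. Per fold, the model is fit on the training set and the
    Pearson correlation between predicted and observed test values is
    recorded. If a spin ensemble is given, the mean test correlation is
    compared one-sided to the same procedure run on spun targets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    folds = list(_cv_folds(geometry, train_frac))
    train_r = np.empty(n)
    test_r = np.empty(n)
    null_sum = np.zeros(spins.n_perm) if spins is not None else None
    Yn = y[spins.assignments].T if spins is not None else None  # (n, n_perm)
    for f, (tr, te) in enumerate(folds):
        Xd_tr = _design(X[tr])
        pinv = np.linalg.pinv(Xd_tr)
        beta = pinv @ y[tr]
        pred_tr = Xd_tr @ beta
        pred_te = _design(X[te]) @ beta
        train_r[f] = _safe_corr(pred_tr, y[tr])
        test_r[f] = _safe_corr(pred_te, y[te])
        if spins is not None:
            Bn = pinv @ Yn[tr]
            Pn = _design(X[te]) @ Bn  # (n_te, n_perm)
            obs = Yn[te]
            pc = Pn - Pn.mean(axis=0)
            oc = obs - obs.mean(axis=0)
            denom = np.sqrt((pc**2).sum(axis=0) * (oc**2).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                rn = np.where(denom > 0, (pc * oc).sum(axis=0) / denom, 0.0)
            null_sum += rn
    mean_test_r = float(test_r.mean())
    p_null = None
    if spins is not None:
        null_means = null_sum / n
        p_null = spin_pvalue(mean_test_r, null_means, tail="one_greater")
    return CVResult(
        train_r=train_r, test_r=test_r, mean_test_r=mean_test_r, p_null=p_null
    )
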