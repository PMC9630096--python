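"""Receptor atlas assembly and its descriptive structure.

The atlas is a region x receptor matrix of z-scored relative densities
(e.g. 100 cortical regions x 19 receptors/transporters). This module
assembles it from per-tracer regional maps, builds the region x region
receptor-similarity matrix (Pearson correlation of regional receptor
fingerprints), fits the exponential decay of similarity with Euclidean
distance, extracts the principal receptor gradient (PC1), and implements
the sensitivity analyses: per-region age regression and
leave-one-receptor-out similarity robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import ParcelGeometry

__all__ = [
    "ReceptorAtlas",
    "DecayFit",
    "combine_tracer_maps",
    "assemble_atlas",
    "receptor_similarity",
    "fit_distance_decay",
    "principal_gradient",
    "class_anova",
    "regress_age",
    "loo_similarity_robustness",
]


def zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """z-score with sample standard deviation (ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance input cannot be z-scored")
    return (x - x.mean(axis=axis, keepdims=True)) / sd


@dataclass
class ReceptorAtlas:
    """Region x receptor matrix of z-scored densities plus receptor metadata.

    ``meta``, when present, is a DataFrame indexed like ``receptor_names``
    with columns such as ``study_n``, ``mean_age`` and class labels
    (excitatory/inhibitory, ionotropic/metabotropic, monoamine,
    Gs/Gi/Gq coupling).
    """

    densities: np.ndarray
    receptor_names: list[str]
    region_ids: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        n, p = self.densities.shape
        if len(self.region_ids) != n:
            raise ValueError("region_ids length does not match densities rows")
        if len(self.receptor_names) != p:
            raise ValueError("receptor_names length does not match densities columns")
        if np.any(~np.isfinite(self.densities)):
            raise ValueError("densities contain non-finite values")
        mu = self.densities.mean(axis=0)
        sd = self.densities.std(axis=0, ddof=1)
        if not (np.allclose(mu, 0, atol=1e-9) and np.allclose(sd, 1, atol=1e-9)):
            raise ValueError("densities columns must be z-scored (mean 0, sd 1, ddof=1)")

    @property
    def n_regions(self) -> int:
        return self.densities.shape[0]

    @property
    def n_receptors(self) -> int:
        return self.densities.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.densities, index=self.region_ids, columns=self.receptor_names
        )


@dataclass
class DecayFit:
    """Parameters of the exponential distance-decay fit a*exp(-b*d) + c."""

    amplitude: float
    rate: float  # 1/mm, >= 0
    offset: float
    rss: float


def combine_tracer_maps(
    maps: list[np.ndarray],
    weights: list[float],
    corr_threshold: float = 0.5,
) -> np.ndarray:
    """Combine multiple tracer maps of one receptor into a single map.

    Each map is z-scored across regions, the z-scored maps are averaged
    with weights proportional to study size, and the result is re-z-scored.
    A warning is raised when any pair of z-scored maps correlates below
    ``corr_threshold`` — different tracers for the same receptor are
    expected to be highly correlated.
    """
    if len(maps) < 2:
        raise ValueError("need at least two maps to combine")
    arrays = [np.asarray(m, dtype=float) for m in maps]
    n = arrays[0].shape[0]
    if any(a.shape != (n,) for a in arrays):
        raise ValueError("all maps must be 1-D with equal length")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(arrays),) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per map")
    z = np.stack([zscore(a) for a in arrays])  # raises on zero variance
    corr = np.corrcoef(z)
    low = corr[np.triu_indices(len(arrays), k=1)] < corr_threshold
    if np.any(low):
        warnings.warn(
            f"tracer maps correlate below {corr_threshold}; check compatibility",
            RuntimeWarning,
            stacklevel=2,
        )
    combined = (w[:, None] * z).sum(axis=0) / w.sum()
    return zscore(combined)


def assemble_atlas(
    tracer_tables: dict[str, np.ndarray] | pd.DataFrame,
    region_ids: list[str] | None = None,
    meta: pd.DataFrame | None = None,
) -> ReceptorAtlas:
    """Assemble the region x receptor atlas from per-receptor regional maps.

    Each receptor's vector is z-scored across regions and the columns are
    concatenated in receptor order.
    """
    if isinstance(tracer_tables, pd.DataFrame):
        names = list(tracer_tables.columns)
        region_ids = [str(r) for r in tracer_tables.index]
        mat = tracer_tables.to_numpy(dtype=float)
    else:
        names = list(tracer_tables.keys())
        lengths = {len(v) for v in tracer_tables.values()}
        if len(lengths) != 1:
            raise ValueError("receptor maps have inconsistent region counts")
        mat = np.column_stack([np.asarray(tracer_tables[k], float) for k in names])
        if region_ids is None:
            region_ids = [f"region{i:03d}" for i in range(mat.shape[0])]
    if np.any(~np.isfinite(mat)):
        rows, cols = np.nonzero(~np.isfinite(mat))
        raise ValueError(
            f"missing value for region {region_ids[rows[0]]}, receptor {names[cols[0]]}"
        )
    for j, name in enumerate(names):
        if mat[:, j].std(ddof=1) == 0:
            raise ValueError(f"receptor '{name}' has zero variance across regions")
    densities = zscore(mat, axis=0)
    return ReceptorAtlas(densities, names, region_ids, meta)


def receptor_similarity(atlas: ReceptorAtlas, min_receptors: int = 3) -> np.ndarray:
    """Region x region receptor similarity matrix.

    Pearson correlation between every pair of regional receptor
    fingerprints (rows of the z-scored density matrix). Symmetric with
    unit diagonal.
    """
    if atlas.n_receptors < min_receptors:
        raise ValueError(
            f"need at least {min_receptors} receptors for row-wise correlation"
        )
    rows = atlas.densities
    var = rows.var(axis=1)
    if np.any(var == 0):
        bad = atlas.region_ids[int(np.flatnonzero(var == 0)[0])]
        raise ValueError(f"region '{bad}' has a zero-variance receptor fingerprint")
    sim = np.corrcoef(rows)
    np.fill_diagonal(sim, 1.0)
    return np.clip(0.5 * (sim + sim.T), -1.0, 1.0)


def fit_distance_decay(
    similarity: np.ndarray, geometry: ParcelGeometry
) -> DecayFit:
    """Fit sim = a*exp(-b*d) + c to the upper-triangle (similarity, distance) pairs.

    Nonlinear least squares with the decay rate bounded at zero;
    initialized from a log-linear regression of the min-shifted similarity
    on distance.
    """
    iu = np.triu_indices(geometry.n_regions, k=1)
    d = geometry.distance[iu]
    s = np.asarray(similarity)[iu]
    if np.any(d <= 0):
        raise ValueError("pairwise distances must be positive")

    # log-linear initialization: log(s - min + eps) ~ log(a) - b*d
    eps = 1e-3
    shifted = s - s.min() + eps
    slope, intercept = np.polyfit(d, np.log(shifted), 1)
    b0 = max(-slope, 1e-6)
    a0 = float(np.exp(intercept))
    c0 = float(s.min())
    p0 = (a0, b0, c0)

    def model(dd, a, b, c):
        return a * np.exp(-b * dd) + c

    try:
        popt, _ = optimize.curve_fit(
            model,
            d,
            s,
            p0=p0,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential decay fit did not converge (initial guess {p0})"
        ) from err
    rss = float(np.sum((s - model(d, *popt)) ** 2))
    return DecayFit(amplitude=float(popt[0]), rate=float(popt[1]),
                    offset=float(popt[2]), rss=rss)


def principal_gradient(atlas: ReceptorAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Principal receptor gradient: PC1 scores of the z-scored atlas.

    Returns the region-wise PC1 score vector and the variance-explained
    fractions of all components. The sign is fixed so that the sum of the
    PC1 loadings is positive.
    """
    X = atlas.densities - atlas.densities.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if not np.any(s > 1e-12):
        raise ValueError("atlas matrix has rank 0")
    varexp = s**2 / np.sum(s**2)
    scores = u[:, 0] * s[0]
    if vt[0].sum() < 0:
        scores = -scores
    return scores, varexp


def class_anova(
    values: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """One-way ANOVA of a regional map across region classes.

    Returns ``(F, p)``; zero within-class variance with distinct means is
    reported as ``(inf, 0.0)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == lab] for lab in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two classes")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every class needs at least two regions (singleton class)")
    within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    means = np.array([g.mean() for g in groups])
    if within == 0 and not np.allclose(means, means[0]):
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def age_residuals(atlas: ReceptorAtlas) -> np.ndarray:
    """Raw per-region residuals of receptor densities regressed on study age.

    For every region separately, the receptor fingerprint is regressed on
    the mean participant age of each receptor's source study (OLS with
    intercept); the residual matrix (not re-z-scored) is returned.
    """
    if atlas.meta is None or "mean_age" not in atlas.meta.columns:
        raise ValueError("atlas.meta with a 'mean_age' column is required")
    ages = atlas.meta["mean_age"].to_numpy(dtype=float)
    if len(np.unique(ages)) < 3:
        raise ValueError("need at least 3 distinct mean ages (slope unidentifiable)")
    A = np.column_stack([np.ones_like(ages), ages])  # (p, 2)
    # residual maker applied to each region's fingerprint (rows of densities)
    hat = A @ np.linalg.solve(A.T @ A, A.T)
    return atlas.densities @ (np.eye(len(ages)) - hat)


def regress_age(atlas: ReceptorAtlas) -> ReceptorAtlas:
    """Age-residualized atlas: :func:`age_residuals` with columns re-z-scored."""
    resid = age_residuals(atlas)
    return ReceptorAtlas(
        zscore(resid, axis=0), list(atlas.receptor_names),
        list(atlas.region_ids), atlas.meta,
    )


def loo_similarity_robustness(atlas: ReceptorAtlas) -> np.ndarray:
    """Leave-one-receptor-out robustness of the similarity matrix.

    For each receptor, recompute the similarity matrix without it and
    correlate its upper triangle with the full-atlas similarity's. Values
    near 1 mean no single receptor drives the similarity structure.
    """
    if atlas.n_receptors < 4:
        raise ValueError("need at least 4 receptors for leave-one-out")
    full = receptor_similarity(atlas)
    iu = np.triu_indices(atlas.n_regions, k=1)
    ref = full[iu]
    out = np.empty(atlas.n_receptors)
    for k in range(atlas.n_receptors):
        keep = [j for j in range(atlas.n_receptors) if j != k]
        sub = ReceptorAtlas(
            zscore(atlas.densities[:, keep], axis=0),
            [atlas.receptor_names[j] for j in keep],
            list(atlas.region_ids),
        )
        loo = receptor_similarity(sub, min_receptors=3)[iu]
        if np.std(loo) == 0 or np.std(ref) == 0:
            out[k] = np.nan  # constant similarity: correlation undefined
        else:
            out[k] = np.corrcoef(ref, loo)[0, 1]
    return out
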