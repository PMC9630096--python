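"""Structure–function coupling and edge-level connectome comparisons.

Communicability of the weighted structural connectome (matrix exponential
of the strength-normalized adjacency) is the structural communication
predictor; regional structure–function coupling is the adjusted R^2 of a
per-region regression of the functional connectivity profile on the
communicability profile. The receptor-informed variant adds the region's
receptor-similarity profile as a second predictor and assesses the gain
against spun similarity profiles (one-sided), FDR-corrected across
regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.sparse.csgraph import shortest_path

from .geometry import ParcelGeometry
from .nulls import SpinEnsemble, fdr_correct

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingResult",
    "communicability",
    "residualize_edges",
    "edge_correlation",
    "regional_coupling",
    "augmented_coupling",
    "alternative_predictor",
]


@dataclass
class CouplingResult:
    """Per-region structure–function coupling with receptor augmentation."""

    r2_base: np.ndarray  # adjusted R^2, communicability-only model
    r2_augmented: np.ndarray  # adjusted R^2, + receptor similarity profile
    delta: np.ndarray  # r2_augmented - r2_base
    p_spin: np.ndarray  # one-sided spin p-value per region
    significant: np.ndarray  # BH-FDR flags
    p_fdr: np.ndarray


def communicability(sc: np.ndarray) -> np.ndarray:
    """Weighted network communicability.

    The matrix exponential of the strength-normalized adjacency
    ``S^(-1/2) A S^(-1/2)`` (S = diagonal of node strengths), summing the
    contributions of all walks between two regions weighted inversely by
    walk-length factorial. An all-zero adjacency returns the identity.
    """
    A = np.asarray(sc, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if np.any(A < 0):
        raise ValueError("structural weights must be non-negative")
    if not A.any():
        return np.eye(n)
    strengths = A.sum(axis=1)
    if np.any(strengths == 0):
        bad = int(np.flatnonzero(strengths == 0)[0])
        raise ValueError(f"region index {bad} is isolated (zero strength)")
    inv_sqrt = 1.0 / np.sqrt(strengths)
    norm = inv_sqrt[:, None] * A * inv_sqrt[None, :]
    comm = expm(norm)
    return 0.5 * (comm + comm.T)


def alternative_predictor(
    sc: np.ndarray, geometry: ParcelGeometry, kind: str = "communicability"
) -> np.ndarray:
    """Pluggable structural predictor for the coupling regressions.

    ``kind`` is ``"communicability"`` (default), ``"shortest_path"``
    (weighted shortest-path length on 1/weight) or ``"euclidean"``
    (centroid distance).
    """
    if kind == "communicability":
        return communicability(sc)
    if kind == "shortest_path":
        with np.errstate(divide="ignore"):
            lengths = np.where(sc > 0, 1.0 / sc, 0.0)
        sp = shortest_path(lengths, method="D", directed=False)
        if np.isinf(sp).any():
            raise ValueError("graph disconnected: shortest paths undefined")
        return sp
    if kind == "euclidean":
        return geometry.distance
    raise ValueError(f"unknown predictor kind '{kind}'")


def _upper(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    return mat[np.triu_indices(n, k=1)]


def residualize_edges(matrix: np.ndarray, geometry: ParcelGeometry) -> np.ndarray:
    """Residualize upper-triangle edge values on Euclidean distance.

    OLS with intercept of the vectorized edges on the corresponding
    centroid distances; returns the residual vector.
    """
    y = _upper(np.asarray(matrix, dtype=float))
    d = _upper(geometry.distance)
    if np.ptp(d) == 0:
        raise ValueError("edge distances are constant; residualization undefined")
    X = np.column_stack([np.ones_like(d), d])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def edge_correlation(
    x_matrix: np.ndarray,
    y_matrix: np.ndarray,
    geometry: ParcelGeometry,
    restrict: str = "all",
) -> tuple[float, int]:
    """Edge-level Pearson correlation after distance regression.

    Both matrices are vectorized over the upper triangle, residualized on
    Euclidean distance, and correlated. ``restrict="connected_only"``
    keeps only pairs with a non-zero entry in ``y_matrix`` (the structural
    connectome convention: correlate over present edges).

    Returns ``(r, n_edges)``.
    """
    x = _upper(np.asarray(x_matrix, dtype=float))
    y = _upper(np.asarray(y_matrix, dtype=float))
    d = _upper(geometry.distance)
    if x.shape != y.shape:
        raise ValueError("matrix shapes do not match")
    if restrict == "connected_only":
        keep = y != 0
    elif restrict == "all":
        keep = np.ones_like(y, dtype=bool)
    else:
        raise ValueError(f"unknown restrict '{restrict}'")
    if keep.sum() < 3:
        raise ValueError("fewer than 3 edges after restriction")
    X = np.column_stack([np.ones(int(keep.sum())), d[keep]])
    rx = x[keep] - X @ np.linalg.lstsq(X, x[keep], rcond=None)[0]
    ry = y[keep] - X @ np.linalg.lstsq(X, y[keep], rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, int(keep.sum())


def _adjusted_r2(r2: float | np.ndarray, n: int, p: int):
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def regional_coupling(comm: np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Structure–function coupling per region.

    For each region i, the functional connectivity profile fc[i, j != i]
    is regressed on the communicability profile comm[i, j != i] (OLS with
    intercept); the adjusted R^2 (n - 1 observations, one predictor) is
    returned. Regions with a zero-variance predictor profile get NaN.
    """
    comm = np.asarray(comm, dtype=float)
    fc = np.asarray(fc, dtype=float)
    n = comm.shape[0]
    if comm.shape != (n, n) or fc.shape != (n, n):
        raise ValueError("matrices must be square with matching shape")
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        x = comm[i, mask]
        y = fc[i, mask]
        if np.ptp(x) == 0:
            logger.warning("region %d: zero-variance communicability profile", i)
            out[i] = np.nan
            continue
        xc = x - x.mean()
        yc = y - y.mean()
        beta = (xc @ yc) / (xc @ xc)
        ss_res = float(((yc - beta * xc) ** 2).sum())
        ss_tot = float((yc**2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[i] = _adjusted_r2(r2, n - 1, 1)
    return out


def _two_predictor_r2(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """R^2 of y on [1, x1, x2]; x2 may be a stack (..., n_obs)."""
    yc = y - y.mean()
    x1c = x1 - x1.mean()
    x2c = x2 - x2.mean(axis=-1, keepdims=True)
    s11 = x1c @ x1c
    s12 = x2c @ x1c
    s22 = np.einsum("...i,...i->...", x2c, x2c)
    c1 = x1c @ yc
    c2 = x2c @ yc
    det = s11 * s22 - s12**2
    ss_tot = yc @ yc
    # (near-)collinear x2 adds nothing: fall back to the single-predictor fit
    collinear = det <= 1e-12 * s11 * s22
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = (s22 * c1 - s12 * c2) / det
        b2 = (s11 * c2 - s12 * c1) / det
        explained = b1 * c1 + b2 * c2
        r2 = explained / ss_tot
    collinear = collinear | ~np.isfinite(r2)
    if np.any(collinear):
        r2_single = (c1**2 / s11) / ss_tot
        r2 = np.where(collinear, r2_single, r2)
    return r2


def augmented_coupling(
    comm: np.ndarray,
    fc: np.ndarray,
    similarity: np.ndarray,
    spins: SpinEnsemble,
    q: float = 0.05,
) -> CouplingResult:
    """Receptor-informed structure–function coupling with spin nulls.

    Per region, the augmented model adds the region's receptor-similarity
    profile as a second predictor. Significance is one-sided: the fraction
    of null augmented adjusted R^2 (similarity profile spun) at or above
    the observed, with BH-FDR across regions.
    """
    comm = np.asarray(comm, dtype=float)
    fc = np.asarray(fc, dtype=float)
    similarity = np.asarray(similarity, dtype=float)
    n = comm.shape[0]
    if not (comm.shape == fc.shape == similarity.shape == (n, n)):
        raise ValueError("matrices must share the same square shape")
    r2_base = np.empty(n)
    r2_aug = np.empty(n)
    p_spin = np.empty(n)
    n_obs = n - 1
    for i in range(n):
        mask = np.arange(n) != i
        y = fc[i, mask]
        x1 = comm[i, mask]
        sim_row = similarity[i]
        x2 = sim_row[mask]
        yc = y - y.mean()
        x1c = x1 - x1.mean()
        r2b = float((x1c @ yc) ** 2 / ((x1c @ x1c) * (yc @ yc)))
        r2_base[i] = _adjusted_r2(r2b, n_obs, 1)
        r2a = float(_two_predictor_r2(y, x1, x2))
        r2_aug[i] = _adjusted_r2(r2a, n_obs, 2)
        # null: spin the full similarity row, then drop the self column
        spun = sim_row[spins.assignments][:, mask]  # (n_perm, n_obs)
        null_r2 = _two_predictor_r2(y, x1, spun)
        null_adj = _adjusted_r2(null_r2, n_obs, 2)
        p_spin[i] = (1 + np.sum(null_adj >= r2_aug[i])) / (1 + spins.n_perm)
    significant, p_fdr = fdr_correct(p_spin, q=q)
    return CouplingResult(
        r2_base=r2_base,
        r2_augmented=r2_aug,
        delta=r2_aug - r2_base,
        p_spin=p_spin,
        significant=significant,
        p_fdr=p_fdr,
    )
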