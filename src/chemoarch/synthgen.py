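"""Synthetic parcellated brain data with planted, recorded ground truth.

Every generator here emulates one input of the analysis pipeline:

* :func:`generate_parcellation` — a stylized two-hemisphere spherical
  parcellation (quasi-uniform Fibonacci lattice per hemisphere) with
  centroids, spherical projections and distances;
* :func:`sample_sa_map` — draws from a zero-mean Gaussian field whose
  covariance decays exponentially with Euclidean centroid distance, the
  canonical model of spatially autocorrelated cortical maps;
* :func:`generate_receptor_atlas` — a region x receptor density matrix
  built from a small number of spatially autocorrelated latent maps plus
  noise, z-scored per receptor, with the planted principal gradient
  recorded;
* :func:`generate_connectomes` — a structural connectome with
  distance-dependent connection probability and a functional connectome
  planted as an affine function of communicability plus (optionally) a
  receptor-similarity contribution;
* :func:`generate_target_maps` — regional target maps (e.g. synthetic band
  power or disorder effect-size maps) that are noisy linear combinations of
  a known active subset of receptors at a controlled signal-to-noise ratio;
* :func:`generate_paired_matrix` — a region x term matrix sharing one
  planted latent component with the receptor atlas at a controlled
  strength, for validating the PLS stage.

All generators are deterministic under their ``seed`` argument: the same
seed and parameters regenerate the data bit-identically. A convenience
:func:`spawn_seeds` fans one global seed out into independent substreams.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .geometry import ParcelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "spawn_seeds",
    "generate_parcellation",
    "sample_sa_map",
    "generate_receptor_atlas",
    "generate_connectomes",
    "generate_target_maps",
    "generate_paired_matrix",
]

def _seed_int(seed) -> int | None:
    """Record an integer seed in ground truth when one was given."""
    return int(seed) if isinstance(seed, (int, np.integer)) else None


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
#: radius (mm) of each hemisphere's sphere (comparable to the scale of
#: surface-based spherical projections of one cortical hemisphere)
HEMI_RADIUS_MM = 70.0
#: distance (mm) of each hemisphere's centre from the midline; the two
#: spheres touch at the origin
HEMI_OFFSET_MM = 70.0


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside a generated dataset.

    Only the fields relevant to the generator that produced the dataset are
    populated; the rest stay ``None``.
    """

    seed: int | None = None
    decay_rate: float | None = None  # 1/mm, covariance length-scale inverse
    gradient: np.ndarray | None = None  # planted principal gradient (PC1)
    latent_maps: np.ndarray | None = None
    mixing_weights: np.ndarray | None = None
    target_weights: np.ndarray | None = None  # receptor-indexed coefficients
    active_set: list[int] | None = field(default=None)
    latent_corr: float | None = None  # planted X-Y shared-component strength
    coupling_beta: float | None = None  # receptor-similarity weight in FC
    noise_sd: float | None = None

    def to_dict(self) -> dict:
        """JSON-serializable dict (arrays become lists)."""
        out = {}
        for key, value in asdict(self).items():
            if isinstance(value, np.ndarray):
                value = value.tolist()
            out[key] = value
        return out


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Fan one global integer seed out into ``n`` independent substreams."""
    return np.random.SeedSequence(seed).spawn(n)


def _fibonacci_sphere(m: int) -> np.ndarray:
    """Quasi-uniform lattice of ``m`` unit vectors on the full sphere."""
    i = np.arange(m)
    x = 1.0 - (2 * i + 1.0) / m
    r = np.sqrt(1.0 - x**2)
    theta = i * _GOLDEN_ANGLE
    return np.column_stack([x, r * np.cos(theta), r * np.sin(theta)])


def generate_parcellation(n_regions: int, seed: int) -> ParcelGeometry:
    """Generate a stylized two-hemisphere spherical parcellation.

    Each hemisphere is a quasi-uniform Fibonacci lattice covering its own
    full sphere of radius ~70 mm, the two spheres sitting side by side at
    x = -70 and x = +70 mm (right hemisphere = x-mirror of the left),
    touching at the origin. This mirrors surface-based spherical
    projections, where each hemisphere's cortex is inflated onto a
    complete sphere: full coverage makes the spin test's
    nearest-rotated-parcel reassignment near-bijective, and each
    hemisphere's spherical coordinates are exactly isometric (up to the
    radius scale) to its Euclidean centroid geometry. A small seeded
    angular jitter about the x axis breaks the lattice's exact regularity;
    it is drawn independently per hemisphere.

    Parameters
    ----------
    n_regions : int
        Total number of parcels; must be even and >= 4 (split equally
        across hemispheres).
    seed : int
        Seed for the jitter; identical seeds give identical geometry.

    Returns
    -------
    ParcelGeometry
    """
    if n_regions < 4 or n_regions % 2 != 0:
        raise ValueError(f"n_regions must be even and >= 4, got {n_regions}")
    m = n_regions // 2
    rng = np.random.default_rng(seed)
    base = _fibonacci_sphere(m)

    def _jitter(points: np.ndarray) -> np.ndarray:
        # rotation about the x axis by a small random angle per parcel;
        # independent per hemisphere so mirrored twins never coincide
        ang = rng.normal(scale=0.08, size=m)
        cos_a, sin_a = np.cos(ang), np.sin(ang)
        out = points.copy()
        out[:, 1] = cos_a * points[:, 1] - sin_a * points[:, 2]
        out[:, 2] = sin_a * points[:, 1] + cos_a * points[:, 2]
        return out

    left = _jitter(base)
    right = _jitter(base * np.array([-1.0, 1.0, 1.0]))

    sphere = np.vstack([left, right])
    sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
    offset = np.repeat([[-HEMI_OFFSET_MM], [HEMI_OFFSET_MM]], m, axis=0)
    centroids = HEMI_RADIUS_MM * sphere + offset * np.array([[1.0, 0.0, 0.0]])
    hemisphere = np.array(["left"] * m + ["right"] * m, dtype=object)
    region_ids = [f"L_{i:03d}" for i in range(m)] + [f"R_{i:03d}" for i in range(m)]
    medial_wall = {
        "left": np.array([1.0, 0.0, 0.0]),  # uncovered cap faces the midline
        "right": np.array([-1.0, 0.0, 0.0]),
    }
    return ParcelGeometry(
        region_ids=region_ids,
        centroids=centroids,
        sphere_coords=sphere,
        hemisphere=hemisphere,
        medial_wall_coord=medial_wall,
    )


def _sa_cholesky(geometry: ParcelGeometry, length_scale: float, sigma: float) -> np.ndarray:
    """Lower Cholesky factor of sigma^2 * exp(-d / length_scale), jittered to PD."""
    cov = sigma**2 * np.exp(-geometry.distance / length_scale)
    cov = 0.5 * (cov + cov.T)
    n = cov.shape[0]
    cov[np.diag_indices(n)] += 1e-10 * np.trace(cov) / n
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        eigmin = float(np.linalg.eigvalsh(cov).min())
        raise np.linalg.LinAlgError(
            "spatial covariance not positive definite after jitter "
            f"(min eigenvalue {eigmin:.3e}); length_scale={length_scale}"
        ) from err


def sample_sa_map(
    geometry: ParcelGeometry,
    length_scale: float,
    sigma: float,
    seed: int | np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Sample spatially autocorrelated regional map(s).

    Draws from a zero-mean Gaussian field with covariance
    ``sigma^2 * exp(-distance / length_scale)`` over the parcel centroids.

    Parameters
    ----------
    geometry : ParcelGeometry
    length_scale : float
        Covariance e-folding distance in mm; must be > 0.
    sigma : float
        Field amplitude (standard deviation at distance 0); must be >= 0.
    seed : int or numpy Generator
    size : int, optional
        If given, return ``size`` independent draws as shape
        ``(size, n_regions)``; otherwise a single ``(n_regions,)`` vector.

    Returns
    -------
    ndarray
    """
    if length_scale <= 0:
        raise ValueError(f"length_scale must be > 0, got {length_scale}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    n = geometry.n_regions
    m = 1 if size is None else size
    if sigma == 0:
        draws = np.zeros((m, n))
    else:
        chol = _sa_cholesky(geometry, length_scale, sigma)
        draws = rng.standard_normal((m, n)) @ chol.T
    return draws[0] if size is None else draws


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    """z-score each column with sample sd (ddof=1); raises on zero variance."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (x - mu) / sd


def generate_receptor_atlas(
    geometry: ParcelGeometry,
    n_receptors: int = 19,
    n_latent: int = 1,
    noise_sd: float = 0.2,
    seed: int = 0,
    length_scale: float = 20.0,
):
    """Generate a synthetic region x receptor density atlas.

    Each receptor map is a linear mixture of ``n_latent`` spatially
    autocorrelated latent maps plus independent Gaussian noise, then
    z-scored per receptor. The latent maps, mixing weights and the planted
    principal gradient (the leading left singular vector of the noiseless
    mixture) are recorded in the returned :class:`GroundTruth`.

    Returns
    -------
    (ReceptorAtlas, GroundTruth)
    """
    from .atlas import ReceptorAtlas

    if not 1 <= n_latent <= n_receptors:
        raise ValueError(f"need 1 <= n_latent <= n_receptors, got {n_latent}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    n = geometry.n_regions
    latent = sample_sa_map(geometry, length_scale, 1.0, rng, size=n_latent)  # (k, n)
    weights = rng.standard_normal((n_latent, n_receptors))
    signal = latent.T @ weights  # (n, p)
    noisy = signal + noise_sd * rng.standard_normal((n, n_receptors))
    densities = _zscore_columns(noisy)

    # planted gradient: leading left singular vector of the centered noiseless signal
    u, s, _ = np.linalg.svd(signal - signal.mean(axis=0), full_matrices=False)
    gradient = u[:, 0] * s[0]

    names = [f"rec{j:02d}" for j in range(n_receptors)]
    atlas = ReceptorAtlas(
        densities=densities,
        receptor_names=names,
        region_ids=list(geometry.region_ids),
        meta=None,
    )
    truth = GroundTruth(
        seed=_seed_int(seed),
        decay_rate=1.0 / length_scale,
        gradient=gradient,
        latent_maps=latent,
        mixing_weights=weights,
        noise_sd=noise_sd,
    )
    return atlas, truth


def generate_connectomes(
    geometry: ParcelGeometry,
    receptor_sim: np.ndarray,
    density: float = 0.2,
    coupling_beta: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    distance_scale: float = 30.0,
):
    """Generate paired structural and functional connectomes.

    Structural edges are drawn (without replacement, Gumbel top-k) with
    probability proportional to ``exp(-distance / distance_scale)`` until
    the target density is reached; weights are uniform on (0.1, 1].
    The functional connectome is planted as

        FC = z(communicability(SC)) + coupling_beta * z(receptor_sim) + noise

    where ``z`` standardizes the off-diagonal entries (an affine map), so
    the receptor-similarity contribution to FC has known strength.

    Returns
    -------
    (sc, fc, truth) : (ndarray, ndarray, GroundTruth)
        Dense symmetric matrices with zero diagonal.
    """
    from .structfunc import communicability

    if not 0 < density < 1:
        raise ValueError(f"density must be in (0, 1), got {density}")
    receptor_sim = np.asarray(receptor_sim, dtype=float)
    n = geometry.n_regions
    if receptor_sim.shape != (n, n):
        raise ValueError("receptor_sim shape does not match geometry")
    if not np.allclose(receptor_sim, receptor_sim.T, atol=1e-8):
        raise ValueError("receptor_sim must be symmetric")
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    m_edges = int(round(density * n_pairs))
    logw = -geometry.distance[iu] / distance_scale
    gumbel = rng.gumbel(size=n_pairs)
    chosen = np.argsort(logw + gumbel)[-m_edges:]

    sc = np.zeros((n, n))
    w = rng.uniform(0.1, 1.0, size=m_edges)
    sc[iu[0][chosen], iu[1][chosen]] = w
    sc = sc + sc.T

    n_comp = connected_components(csr_matrix(sc != 0), directed=False)[0]
    if n_comp > 1:
        warnings.warn(
            f"generated structural connectome is disconnected ({n_comp} components)",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("synthetic SC disconnected: %d components", n_comp)

    comm = communicability(sc)

    def _z_offdiag(mat: np.ndarray) -> np.ndarray:
        vals = mat[iu]
        return (mat - vals.mean()) / vals.std(ddof=1)

    fc = _z_offdiag(comm) + coupling_beta * _z_offdiag(receptor_sim)
    if noise_sd > 0:
        eps = rng.standard_normal((n, n)) * noise_sd
        fc = fc + np.triu(eps, 1) + np.triu(eps, 1).T
    np.fill_diagonal(fc, 0.0)
    truth = GroundTruth(seed=_seed_int(seed), coupling_beta=coupling_beta, noise_sd=noise_sd)
    return sc, fc, truth


def generate_target_maps(
    atlas,
    active_set,
    snr: float = 10.0,
    n_maps: int = 1,
    seed: int = 0,
):
    """Generate regional target maps driven by a known receptor subset.

    Each map is ``X[:, active_set] @ w + noise`` with Gaussian noise scaled
    so that the ratio of signal variance to noise variance equals ``snr``
    (``snr=inf`` gives noiseless maps). Active weights have random sign and
    magnitude uniform on [0.5, 1.5] — bounded away from zero so that every
    receptor declared active genuinely contributes (a near-zero weight
    would make it de facto inactive). True weights (zero outside the
    active set) are recorded.

    Returns
    -------
    (maps, truth) : (ndarray shape (n_regions, n_maps), GroundTruth)
    """
    active = np.atleast_1d(np.asarray(active_set, dtype=int))
    if active.size == 0:
        raise ValueError("active_set must be a non-empty subset of receptors")
    if snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    X = atlas.densities
    n, p = X.shape
    if active.min() < 0 or active.max() >= p:
        raise ValueError("active_set indices out of range")
    rng = np.random.default_rng(seed)
    weights_full = np.zeros((p, n_maps))
    w = rng.uniform(0.5, 1.5, size=(active.size, n_maps)) * rng.choice(
        [-1.0, 1.0], size=(active.size, n_maps)
    )
    weights_full[active] = w
    signal = X[:, active] @ w  # (n, n_maps)
    sig_sd = signal.std(axis=0, ddof=1)
    noise_sd = np.zeros(n_maps) if np.isinf(snr) else sig_sd / np.sqrt(snr)
    maps = signal + noise_sd * rng.standard_normal((n, n_maps))
    truth = GroundTruth(
        seed=_seed_int(seed),
        target_weights=weights_full,
        active_set=active.tolist(),
        noise_sd=float(np.mean(noise_sd)),
    )
    return maps, truth


def generate_paired_matrix(
    atlas,
    geometry: ParcelGeometry,
    n_terms: int = 24,
    latent_corr: float = 0.5,
    seed: int = 0,
    length_scale: float = 20.0,
):
    """Generate a region x term matrix sharing a latent component with the atlas.

    Each term column is ``latent_corr * s_t * u + sqrt(1 - latent_corr^2) * e_t``
    where ``u`` is the atlas's principal-gradient score (z-scored),
    ``s_t`` a random sign, and ``e_t`` an independent spatially
    autocorrelated noise map (z-scored); columns are re-z-scored. At
    ``latent_corr=1`` the cross-covariance with the atlas is rank one; at
    ``latent_corr=0`` the two blocks are independent.

    Returns
    -------
    (terms, truth) : (ndarray shape (n_regions, n_terms), GroundTruth)
    """
    if not 0 <= latent_corr <= 1:
        raise ValueError(f"latent_corr must be in [0, 1], got {latent_corr}")
    from .atlas import principal_gradient

    rng = np.random.default_rng(seed)
    u, _ = principal_gradient(atlas)
    u = (u - u.mean()) / u.std(ddof=1)
    n = geometry.n_regions
    noise = sample_sa_map(geometry, length_scale, 1.0, rng, size=n_terms).T  # (n, t)
    noise = _zscore_columns(noise)
    signs = rng.choice([-1.0, 1.0], size=n_terms)
    terms = latent_corr * u[:, None] * signs + np.sqrt(1 - latent_corr**2) * noise
    if latent_corr == 1.0:
        terms = u[:, None] * signs  # degenerate: pure shared component
    terms = _zscore_columns(terms)
    truth = GroundTruth(seed=_seed_int(seed), latent_corr=latent_corr, gradient=u)
    return terms, truth
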