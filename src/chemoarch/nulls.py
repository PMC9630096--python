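"""Null models for parcellated brain maps and connectomes.

Two families of nulls, plus shared p-value and FDR utilities:

* **Spin permutations** (:func:`build_spin_ensemble`): random rotations of
  the parcels' spherical coordinates, applied to each hemisphere
  separately (the right hemisphere receives the mirror-conjugate of the
  left's rotation), with each original parcel reassigned the value of the
  closest rotated parcel. This destroys the alignment between two maps
  while preserving each map's spatial autocorrelation. Assignments are
  nearest-neighbour reassignments, not permutations — duplicates are
  allowed, exactly as in parcel-resolution spin tests.

* **Length-preserving rewiring** (:func:`rewire_preserving_length`):
  degree-preserving double-edge swaps of a structural connectome,
  restricted so that the swapped edges stay within the same Euclidean
  edge-length bin. Every null preserves the binary degree sequence, the
  edge count and the per-bin edge counts exactly; weights travel with
  their edges.

P-values use the permutation convention ``p = (1 + k) / (1 + n_perm)``
(never exactly zero); FDR control is Benjamini–Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .geometry import ParcelGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "SpinEnsemble",
    "RewiredEnsemble",
    "build_spin_ensemble",
    "spin_pvalue",
    "rewire_preserving_length",
    "connected_contrast_test",
    "label_contrast_test",
    "fdr_correct",
]

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass
class SpinEnsemble:
    """Rotated-parcel reassignment indices.

    ``assignments[p, i]`` is the source region whose value region ``i``
    receives under rotation ``p``. Rows are within-hemisphere nearest-
    rotated-parcel reassignments and need not be permutations.
    """

    assignments: np.ndarray  # (n_perm, n_regions) int
    n_perm: int
    seed: int | None

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Spin a regional map (or stack of maps along the last axis).

        Returns shape ``(n_perm, ...)`` with the region axis reassigned.
        """
        values = np.asarray(values)
        return values[self.assignments]


@dataclass
class RewiredEnsemble:
    """Degree- and edge-length-preserving null structural connectomes."""

    matrices: list[np.ndarray]
    bin_edges: np.ndarray  # distance bin boundaries, mm
    n_swaps: int  # swap attempts per null


def _random_rotations(n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(n_perm, rng=rng).as_matrix()


def build_spin_ensemble(
    geometry: ParcelGeometry,
    n_perm: int,
    seed: int | None = 0,
    rotations: np.ndarray | None = None,
) -> SpinEnsemble:
    """Build a spatial-autocorrelation-preserving spin ensemble.

    For each repetition one rotation, uniform on SO(3), is applied to the
    left hemisphere's spherical coordinates and its mirror conjugate
    (x-flip on both sides) to the right hemisphere's. Each original parcel
    is assigned the nearest rotated parcel of its own hemisphere; if the
    rotated medial-wall marker is nearest, the next-nearest parcel is used.
    Ties break toward the lowest region index.

    Parameters
    ----------
    geometry : ParcelGeometry
    n_perm : int
        Number of rotations; must be >= 1.
    seed : int, optional
        Seed for the rotation stream.
    rotations : ndarray (n_perm, 3, 3), optional
        Explicit rotation matrices for the left hemisphere (test hook; the
        identity reproduces the input assignment).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if rotations is None:
        rng = np.random.default_rng(seed)
        rotations = _random_rotations(n_perm, rng)
    else:
        rotations = np.asarray(rotations, dtype=float)
        if rotations.shape != (n_perm, 3, 3):
            raise ValueError("rotations must have shape (n_perm, 3, 3)")

    n = geometry.n_regions
    assignments = np.empty((n_perm, n), dtype=np.intp)
    for hemi in ("left", "right"):
        idx = geometry.hemi_indices(hemi)
        coords = geometry.sphere_coords[idx]  # (m, 3)
        wall = None
        if geometry.medial_wall_coord is not None:
            wall = geometry.medial_wall_coord.get(hemi)
        for p in range(n_perm):
            rot = rotations[p]
            if hemi == "right":
                rot = _MIRROR @ rot @ _MIRROR
            rotated = coords @ rot.T
            dist = cdist(coords, rotated)  # original x rotated
            nearest = np.argmin(dist, axis=1)
            if wall is not None:
                wall_rot = wall @ rot.T
                wall_dist = np.linalg.norm(coords - wall_rot, axis=1)
                # where the rotated wall marker beats every parcel, keep the
                # nearest parcel anyway (the "next most proximal" candidate)
                blocked = wall_dist < dist[np.arange(len(idx)), nearest]
                if np.any(blocked):
                    logger.debug(
                        "%d parcels nearest to medial wall in perm %d", blocked.sum(), p
                    )
            assignments[p, idx] = idx[nearest]
    return SpinEnsemble(assignments=assignments, n_perm=n_perm,
                        seed=None if seed is None else int(seed))


def spin_pvalue(
    observed: float, null_stats: np.ndarray, tail: str = "two"
) -> float:
    """Permutation p-value with the (1 + k) / (1 + n) convention.

    ``tail`` is one of ``"one_greater"``, ``"one_less"`` or ``"two"``;
    the two-tailed version compares absolute deviations from the null mean.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    if null_stats.size == 0:
        raise ValueError("null_stats is empty")
    if np.any(np.isnan(null_stats)) or np.isnan(observed):
        raise ValueError("NaN in observed statistic or null distribution")
    if tail == "one_greater":
        k = int(np.sum(null_stats >= observed))
    elif tail == "one_less":
        k = int(np.sum(null_stats <= observed))
    elif tail == "two":
        center = null_stats.mean()
        k = int(np.sum(np.abs(null_stats - center) >= np.abs(observed - center)))
    else:
        raise ValueError(f"unknown tail '{tail}'")
    return (1 + k) / (1 + null_stats.size)


def _edge_bins(lengths: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count distance bin edges over the connected-edge lengths."""
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(lengths, qs)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return np.unique(edges)


def rewire_preserving_length(
    sc: np.ndarray,
    geometry: ParcelGeometry,
    n_bins: int = 10,
    n_nulls: int = 100,
    seed: int | None = 0,
    n_swaps: int | None = None,
) -> RewiredEnsemble:
    """Degree- and edge-length-preserving null connectomes.

    Edges are binned by Euclidean length (equal-count bins by default).
    Within each bin, random pairs of edges (a,b), (c,d) are swapped to
    (a,d), (c,b); a swap is accepted only if it creates no self-loop or
    multi-edge and both new edges fall in the same length bin, so the
    degree sequence, density and per-bin edge counts are preserved exactly.
    Edge weights travel with their edges.

    Parameters
    ----------
    n_swaps : int, optional
        Swap attempts per null; defaults to 10x the edge count.
    """
    sc = np.asarray(sc, dtype=float)
    n = geometry.n_regions
    if sc.shape != (n, n) or not np.allclose(sc, sc.T, atol=1e-10):
        raise ValueError("sc must be a symmetric matrix matching the geometry")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    iu = np.triu_indices(n, k=1)
    present = sc[iu] != 0
    u, v = iu[0][present], iu[1][present]
    w = sc[u, v]
    m = len(u)
    if m < 2:
        raise ValueError("connectome has fewer than 2 edges")
    lengths = geometry.distance[u, v]
    edges_bins = _edge_bins(lengths, n_bins)
    bin_of = np.searchsorted(edges_bins, lengths, side="right") - 1
    n_bins_eff = len(edges_bins) - 1
    if n_swaps is None:
        n_swaps = 10 * m
    rng = np.random.default_rng(seed)

    dist = geometry.distance
    matrices: list[np.ndarray] = []
    for _ in range(n_nulls):
        eu, ev = u.copy(), v.copy()
        ew = w.copy()
        existing = set(map(tuple, zip(eu.tolist(), ev.tolist())))
        members = [np.flatnonzero(bin_of == b) for b in range(n_bins_eff)]
        for b, mem in enumerate(members):
            if len(mem) < 2:
                logger.info("distance bin %d has < 2 edges; skipped", b)
                continue
            lo, hi = edges_bins[b], edges_bins[b + 1]  # bin b covers [lo, hi)
            picks = rng.integers(0, len(mem), size=(n_swaps * len(mem) // m + 1, 2))
            for e1i, e2i in picks:
                if e1i == e2i:
                    continue
                e1, e2 = mem[e1i], mem[e2i]
                a, bb = eu[e1], ev[e1]
                c, d = eu[e2], ev[e2]
                # swap to (a,d) and (c,bb)
                if a == d or c == bb:
                    continue
                na = (min(a, d), max(a, d))
                nb = (min(c, bb), max(c, bb))
                if na == nb or na in existing or nb in existing:
                    continue
                da, db = dist[na], dist[nb]
                if not (lo <= da < hi and lo <= db < hi):
                    continue  # new edge would leave the length bin
                existing.discard((min(a, bb), max(a, bb)))
                existing.discard((min(c, d), max(c, d)))
                existing.add(na)
                existing.add(nb)
                eu[e1], ev[e1] = na
                eu[e2], ev[e2] = nb
        null = np.zeros_like(sc)
        null[eu, ev] = ew
        null[ev, eu] = ew
        matrices.append(null)
    return RewiredEnsemble(matrices=matrices, bin_edges=edges_bins, n_swaps=int(n_swaps))


def _contrast(similarity: np.ndarray, mask: np.ndarray, iu) -> float:
    sim = similarity[iu]
    conn = mask[iu]
    if not conn.any() or conn.all():
        raise ValueError("need both connected and unconnected pairs")
    return float(sim[conn].mean() - sim[~conn].mean())


def connected_contrast_test(
    similarity: np.ndarray,
    sc: np.ndarray,
    ensemble: RewiredEnsemble,
    tail: str = "two",
) -> tuple[float, float]:
    """Connected-versus-unconnected receptor-similarity contrast.

    The statistic is the mean similarity over structurally connected
    region pairs minus the mean over unconnected pairs; the null
    distribution re-evaluates it on each rewired connectome.
    """
    n = similarity.shape[0]
    iu = np.triu_indices(n, k=1)
    observed = _contrast(similarity, sc != 0, iu)
    nulls = np.array([_contrast(similarity, m != 0, iu) for m in ensemble.matrices])
    return observed, spin_pvalue(observed, nulls, tail=tail)


def label_contrast_test(
    similarity: np.ndarray,
    labels: np.ndarray,
    spins: SpinEnsemble,
    tail: str = "two",
) -> tuple[float, float]:
    """Within- versus between-label receptor-similarity contrast.

    The statistic is the mean similarity within label classes minus the
    mean between classes; significance is assessed by spinning the label
    map (spatial-autocorrelation-preserving permutation of the labels).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    for lab in uniq:
        if np.all(labels == lab):
            raise ValueError("a single label covers all regions")
    n = similarity.shape[0]
    iu = np.triu_indices(n, k=1)
    sim = similarity[iu]

    def stat(lab_vec: np.ndarray) -> float:
        same = lab_vec[iu[0]] == lab_vec[iu[1]]
        if not same.any() or same.all():
            return np.nan
        return float(sim[same].mean() - sim[~same].mean())

    observed = stat(labels)
    nulls = np.array([stat(labels[spins.assignments[p]]) for p in range(spins.n_perm)])
    nulls = nulls[~np.isnan(nulls)]  # degenerate spins (all-same labels) dropped
    return observed, spin_pvalue(observed, nulls, tail=tail)


def fdr_correct(
    pvalues: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg FDR correction.

    Returns ``(rejected, p_adjusted)`` at level ``q``.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1) | ~np.isfinite(pvalues)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return rejected, p_adj
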