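"""Parcel geometry: centroids, spherical projections and pairwise distances.

All downstream machinery (distance-decay fits, spin permutations,
edge-length-binned rewiring, distance-dependent cross-validation) consumes a
:class:`ParcelGeometry`: per-region Euclidean centroids in mm, a per-region
unit vector on the hemisphere's spherical projection, hemisphere labels and
the dense Euclidean distance matrix between centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["ParcelGeometry"]


@dataclass
class ParcelGeometry:
    """Geometry of a cortical parcellation.

    Parameters
    ----------
    region_ids : sequence of str
        Ordered region labels; the order defines the row/column order of
        every matrix in the pipeline.
    centroids : ndarray, shape (n_regions, 3)
        Euclidean parcel centroids in mm.
    sphere_coords : ndarray, shape (n_regions, 3)
        Unit vectors locating each parcel on the spherical projection used
        by the spin test.
    hemisphere : ndarray of str, shape (n_regions,)
        ``"left"`` or ``"right"`` per region.
    medial_wall_coord : dict or None
        Optional unit 3-vector per hemisphere marking the medial wall on
        the sphere; parcels whose nearest rotated point is the wall are
        reassigned to the next-nearest rotated parcel.
    """

    region_ids: list[str]
    centroids: np.ndarray
    sphere_coords: np.ndarray
    hemisphere: np.ndarray
    medial_wall_coord: dict[str, np.ndarray] | None = None
    distance: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        n = len(self.region_ids)
        if self.centroids.shape != (n, 3):
            raise ValueError(f"centroids must be ({n}, 3), got {self.centroids.shape}")
        if self.sphere_coords.shape != (n, 3):
            raise ValueError(
                f"sphere_coords must be ({n}, 3), got {self.sphere_coords.shape}"
            )
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere_coords rows must have unit norm (atol 1e-9)")
        for hemi in ("left", "right"):
            if int(np.sum(self.hemisphere == hemi)) < 2:
                raise ValueError(f"hemisphere '{hemi}' must contain at least 2 regions")
        if self.distance is None:
            self.distance = squareform(pdist(self.centroids))
        else:
            self.distance = np.asarray(self.distance, dtype=float)
            self._check_distance()

    def _check_distance(self) -> None:
        d = self.distance
        if d.shape != (self.n_regions, self.n_regions):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        ref = squareform(pdist(self.centroids))
        if not np.allclose(d, ref, atol=1e-6):
            raise ValueError("distance matrix inconsistent with centroids")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def hemi_indices(self, hemi: str) -> np.ndarray:
        """Integer indices of the regions in hemisphere ``hemi``."""
        return np.flatnonzero(self.hemisphere == hemi)
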