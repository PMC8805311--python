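"""Geometric comparison of binary segmentations.

Implements the overlap and surface-distance metrics used to score an
auto-segmented structure against a reference delineation: Dice similarity
coefficient, average Hausdorff distance and percentile Hausdorff distance,
plus the slice restriction applied to tubular organs (rectum) whose
superior extent is ambiguous against neighbouring bowel.

Boundary points are the centers of mask voxels with at least one
face-adjacent (6-connectivity) background voxel; a voxel on the array edge
counts as boundary. Distances are Euclidean in mm, spacing-aware.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import BinaryMask3D

__all__ = [
    "SurfaceDistanceSet",
    "dsc",
    "boundary_points",
    "surface_distances",
    "hd_avg",
    "hd_percentile",
    "restrict_to_reference_slices",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclasses.dataclass
class SurfaceDistanceSet:
    """Directed boundary-point distances between two masks, in mm."""

    ref_to_test: np.ndarray
    test_to_ref: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.ref_to_test, self.test_to_ref])


def dsc(a: BinaryMask3D, b: BinaryMask3D) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.

    Defined as 1.0 (with a warning) when both masks are empty.
    """
    a.require_same_geometry(b, "dsc")
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        warnings.warn("dsc of two empty masks; returning 1.0 by convention")
        return 1.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def boundary_points(mask: BinaryMask3D) -> np.ndarray:
    """Boundary voxel centers in mm, shape ``(n, 3)`` in ``(z, y, x)`` order."""
    if mask.is_empty():
        raise ValueError("boundary_points of an empty mask is undefined")
    eroded = ndimage.binary_erosion(mask.values, structure=_FACE_STRUCT)
    surf = mask.values & ~eroded
    idx = np.argwhere(surf)
    return mask.index_to_mm(idx)


def surface_distances(a: BinaryMask3D, b: BinaryMask3D) -> SurfaceDistanceSet:
    """For each boundary point of one mask, the distance to the other's nearest
    boundary point, both directions."""
    a.require_same_geometry(b, "surface_distances")
    pa = boundary_points(a)
    pb = boundary_points(b)
    d_ab = cKDTree(pb).query(pa, workers=-1)[0]
    d_ba = cKDTree(pa).query(pb, workers=-1)[0]
    return SurfaceDistanceSet(d_ab, d_ba, a.spacing)


def hd_avg(
    a: BinaryMask3D, b: BinaryMask3D, symmetrization: str = "pooled"
) -> float:
    """Average Hausdorff distance in mm.

    ``symmetrization='pooled'`` (default) averages the union of both directed
    distance lists; ``'max_of_means'`` takes the larger of the two directed
    means — both conventions appear in the segmentation literature.
    """
    sd = surface_distances(a, b)
    if symmetrization == "pooled":
        return float(sd.pooled.mean())
    if symmetrization == "max_of_means":
        return float(max(sd.ref_to_test.mean(), sd.test_to_ref.mean()))
    raise ValueError(f"unknown symmetrization {symmetrization!r}")


def hd_percentile(a: BinaryMask3D, b: BinaryMask3D, q: float = 95.0) -> float:
    """q-th percentile (linear interpolation) of the pooled symmetric
    boundary-distance list; ``q=100`` is the classical Hausdorff distance."""
    if not 0 < q <= 100:
        raise ValueError(f"percentile q must be in (0, 100], got {q}")
    sd = surface_distances(a, b)
    return float(np.percentile(sd.pooled, q))


def restrict_to_reference_slices(
    pred: BinaryMask3D, ref: BinaryMask3D
) -> BinaryMask3D:
    """Remove prediction voxels on axial slices where the reference is empty.

    Applied to the rectum before geometric scoring so over-segmentation into
    the (uncontoured) colon above the reference's extent is not penalized.
    """
    pred.require_same_geometry(ref, "restrict_to_reference_slices")
    keep = ref.values.any(axis=(1, 2))
    vals = pred.values & keep[:, None, None]
    return BinaryMask3D(vals, pred.spacing, pred.origin)
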