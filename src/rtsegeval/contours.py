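"""Planar contour sets and conversion to/from binary masks.

Structures are stored the way RT structure sets represent them: per axial
slice, one or more closed planar polygons with vertices in patient-space mm.
Rasterization uses the even-odd rule on voxel centers, so a polygon listed
inside another one on the same slice punches a hole. Extraction traces the
0.5 iso-level of the binary field per slice, which makes
``rasterize(extract(mask))`` a near-identity on smoothly shaped organs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from skimage import measure

from .grids import BinaryMask3D, Image3D

__all__ = ["ContourSlice", "ContourSet", "rasterize_contours", "extract_contours"]


@dataclasses.dataclass
class ContourSlice:
    """All closed polygons of one structure on one axial plane.

    ``polygons`` is a list of ``(n, 2)`` arrays of ``(x, y)`` vertices in mm.
    Polygons are implicitly closed (last vertex connects back to the first).
    """

    z: float
    polygons: list[np.ndarray]

    def __post_init__(self) -> None:
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError(
                    "each polygon must be an (n>=3, 2) array of (x, y) mm vertices"
                )


@dataclasses.dataclass
class ContourSet:
    """Named structures as per-slice closed planar polygons."""

    structures: dict[str, list[ContourSlice]]

    def names(self) -> list[str]:
        return list(self.structures)

    def slices(self, name: str) -> list[ContourSlice]:
        return self.structures[name]


def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized over points.

    Points exactly on an edge follow the half-open convention of the crossing
    test; with voxel centers this is measure-zero and irrelevant in practice.
    """
    x0 = poly[:, 0]
    y0 = poly[:, 1]
    x1 = np.roll(x0, -1)
    y1 = np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ex0, ey0, ex1, ey1 in zip(x0, y0, x1, y1):
        if ey0 == ey1:
            continue  # horizontal edge never crossed by a horizontal ray rule
        cond = (ey0 > py) != (ey1 > py)
        # x coordinate of the edge at each point's y
        with np.errstate(invalid="ignore"):
            xin = ex0 + (py - ey0) * (ex1 - ex0) / (ey1 - ey0)
        inside ^= cond & (px < xin)
    return inside


def _rasterize_plane(
    slice_: ContourSlice, geom: Image3D
) -> np.ndarray:
    """Even-odd rasterization of one contoured plane onto the (y, x) lattice."""
    _, ys, xs = geom.axis_coords()
    plane = np.zeros((len(ys), len(xs)), dtype=bool)
    for poly in slice_.polygons:
        # restrict to the polygon bounding box for speed
        j0, j1 = np.searchsorted(ys, [poly[:, 1].min(), poly[:, 1].max()])
        i0, i1 = np.searchsorted(xs, [poly[:, 0].min(), poly[:, 0].max()])
        j1 = min(j1 + 1, len(ys))
        i1 = min(i1 + 1, len(xs))
        if j0 >= j1 or i0 >= i1:
            continue
        gy, gx = np.meshgrid(ys[j0:j1], xs[i0:i1], indexing="ij")
        plane[j0:j1, i0:i1] ^= _points_in_polygon(gx, gy, poly)
    return plane


def rasterize_contours(
    contours: ContourSet, geometry: Image3D
) -> dict[str, BinaryMask3D]:
    """Convert a contour set to binary masks on ``geometry``'s lattice.

    A voxel belongs to a structure iff its center lies inside an odd number
    of that structure's polygons on the corresponding plane (even-odd rule).
    Grid slices that fall between contoured planes take the occupancy of the
    nearest contoured plane, provided it is within half the structure's
    inter-plane spacing — the nearest-neighbour z-fill used when 3 mm contour
    planes are mapped onto a 1 mm grid.
    """
    out: dict[str, BinaryMask3D] = {}
    zs = geometry.axis_coords()[0]
    for name, slices in contours.structures.items():
        vol = np.zeros(geometry.shape, dtype=bool)
        if not slices:
            warnings.warn(f"structure {name!r} has no contours; mask is empty")
            out[name] = BinaryMask3D(vol, geometry.spacing, geometry.origin)
            continue
        slices = sorted(slices, key=lambda s: s.z)
        plane_z = np.array([s.z for s in slices])
        lo = plane_z.min() - geometry.spacing[0]
        hi = plane_z.max() + geometry.spacing[0]
        if hi < zs[0] or lo > zs[-1]:
            raise ValueError(
                f"structure {name!r}: contour planes z in "
                f"[{plane_z.min():.1f}, {plane_z.max():.1f}] mm lie outside the "
                f"target grid extent [{zs[0]:.1f}, {zs[-1]:.1f}] mm"
            )
        if len(plane_z) > 1:
            half_gap = 0.5 * float(np.median(np.diff(plane_z)))
        else:
            half_gap = 0.5 * geometry.spacing[0]
        half_gap = max(half_gap, 0.5 * geometry.spacing[0])
        planes = [_rasterize_plane(s, geometry) for s in slices]
        nearest = np.searchsorted(plane_z, zs)
        for k, zk in enumerate(zs):
            cands = [c for c in (nearest[k] - 1, nearest[k]) if 0 <= c < len(plane_z)]
            if not cands:
                continue
            c = min(cands, key=lambda c: abs(plane_z[c] - zk))
            if abs(plane_z[c] - zk) <= half_gap + 1e-9:
                vol[k] = planes[c]
        out[name] = BinaryMask3D(vol, geometry.spacing, geometry.origin)
    return out


def extract_contours(mask: BinaryMask3D, name: str = "structure") -> ContourSet:
    """Trace closed boundary polygons of ``mask`` at the 0.5 iso-level.

    One polygon per connected boundary loop per axial slice; inner loops
    (holes) are emitted as additional polygons and round-trip through the
    even-odd rasterization rule. Empty masks yield an empty slice list.
    """
    slices: list[ContourSlice] = []
    zs, ys, xs = mask.axis_coords()
    sy, sx = mask.spacing[1], mask.spacing[2]
    for k in range(mask.shape[0]):
        plane = mask.values[k]
        if not plane.any():
            continue
        # pad so structures touching the grid edge still produce closed loops
        padded = np.pad(plane.astype(float), 1)
        loops = measure.find_contours(padded, 0.5)
        polys = []
        for loop in loops:
            # drop find_contours' repeated closing vertex; closure is implicit
            if len(loop) > 1 and np.allclose(loop[0], loop[-1]):
                loop = loop[:-1]
            if len(loop) < 3:
                continue
            yy = ys[0] + (loop[:, 0] - 1.0) * sy
            xx = xs[0] + (loop[:, 1] - 1.0) * sx
            polys.append(np.column_stack([xx, yy]))
        if polys:
            slices.append(ContourSlice(z=float(zs[k]), polygons=polys))
    return ContourSet(structures={name: slices})
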