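"""Regular 3D voxel lattices: images, binary masks and dose grids.

Axis convention (used consistently across the package):

* arrays are indexed ``values[z, y, x]``;
* ``+z`` is superior (SI axis), ``+y`` is posterior (AP axis), ``+x`` is
  patient-left (ML axis) — i.e. the DICOM LPS patient frame;
* ``spacing`` and ``origin`` are given per axis in the same ``(z, y, x)``
  order, in millimetres;
* ``origin`` is the patient-space position of the *center* of voxel
  ``(0, 0, 0)``; a voxel spans the half-open cube centered on its center.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np

__all__ = ["Image3D", "BinaryMask3D", "DoseGrid", "GeometryError"]


class GeometryError(ValueError):
    """Two grids that should share a lattice do not."""


@dataclasses.dataclass
class Image3D:
    """A scalar volume on a regular axis-aligned lattice.

    Parameters
    ----------
    values
        3D array indexed ``[z, y, x]``.
    spacing
        Voxel size in mm per axis, ``(sz, sy, sx)``. Must be positive.
    origin
        Patient-space mm coordinates of the center of voxel ``(0, 0, 0)``,
        in ``(z, y, x)`` order.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "Image3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other: "Image3D", what: str = "operand") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"{what} geometry mismatch: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis mm coordinates of voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) ``(z, y, x)`` indices to mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        """Map mm coordinates to fractional ``(z, y, x)`` indices."""
        mm = np.asarray(mm, dtype=float)
        return (mm - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy_with(self, values: np.ndarray) -> "Image3D":
        return dataclasses.replace(self, values=values)

    def __iter__(self) -> Iterator:  # guard against accidental unpacking
        raise TypeError("Image3D is not iterable")


@dataclasses.dataclass
class BinaryMask3D(Image3D):
    """A boolean structure mask sharing the :class:`Image3D` geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.dtype != bool:
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be boolean or 0/1")
            self.values = self.values.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.values.any())


@dataclasses.dataclass
class DoseGrid(Image3D):
    """Absolute dose in Gy on an :class:`Image3D` lattice; values >= 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError(
                f"dose values must be non-negative, min={self.values.min():.3g} Gy"
            )
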