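"""Dose-volume metrics: DVH parameters, margin expansion, conformity, ICRU 83.

The DVH is built by exact voxel counting (no sub-voxel partial volumes): the
cumulative curve at dose d is the fraction of structure voxels receiving at
least d. D- and V-parameters are read off the curve with linear interpolation
between the sampled dose points, so halving the bin width moves D98/D2 by
less than one bin.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .grids import BinaryMask3D, DoseGrid

__all__ = [
    "DVHCurve",
    "MarginSpec",
    "cumulative_dvh",
    "dvh_D",
    "dvh_V",
    "expand_margin",
    "paddick_ci",
    "icru83_check",
]


@dataclasses.dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``volume_fraction[i]`` is the fraction of the structure receiving at
    least ``dose_gy[i]``; the curve starts at 1 for dose 0 and is
    non-increasing.
    """

    dose_gy: np.ndarray
    volume_fraction: np.ndarray
    volume_cm3: float

    def __post_init__(self) -> None:
        self.dose_gy = np.asarray(self.dose_gy, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_gy.shape != self.volume_fraction.shape:
            raise ValueError("dose and volume arrays must have the same length")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


@dataclasses.dataclass
class MarginSpec:
    """Anisotropic expansion margins in mm per anatomical direction.

    Directions follow the package axis convention: posterior = +y,
    anterior = -y, superior = +z, inferior = -z, left = +x, right = -x.
    """

    anterior: float = 6.0
    posterior: float = 5.0
    left: float = 6.0
    right: float = 6.0
    superior: float = 6.0
    inferior: float = 6.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"margin {f.name} must be >= 0")

    @classmethod
    def isotropic(cls, mm: float) -> "MarginSpec":
        return cls(mm, mm, mm, mm, mm, mm)


def cumulative_dvh(
    dose: DoseGrid, mask: BinaryMask3D, bin_width: float = 0.01
) -> DVHCurve:
    """Exact voxel-counting cumulative DVH with dose points every ``bin_width`` Gy."""
    dose.require_same_geometry(mask, "cumulative_dvh")
    if mask.is_empty():
        raise ValueError("cannot build a DVH for an empty structure")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = dose.values[mask.values]
    top = float(vals.max()) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    # fraction receiving >= each edge: 1 - ECDF(edge^-)
    counts, _ = np.histogram(vals, bins=np.append(edges, np.inf))
    frac = 1.0 - np.cumsum(np.append(0, counts[:-1])) / vals.size
    return DVHCurve(edges, frac[: len(edges)], mask.volume_cm3)


def dvh_D(curve: DVHCurve, p: float) -> float:
    """D_p%: minimum dose (Gy) received by the hottest p% of the structure."""
    if not 0 < p <= 100:
        raise ValueError(f"p must be in (0, 100], got {p}")
    target = p / 100.0
    v = curve.volume_fraction
    d = curve.dose_gy
    if target <= v[-1]:
        return float(d[-1])
    if target >= v[0]:
        return float(d[0])
    # v is non-increasing: interpolate the inverse curve
    return float(np.interp(-target, -v, d))


def dvh_V(
    curve: DVHCurve,
    threshold: float,
    percent_of: float | None = None,
) -> float:
    """V_X: percent of the structure receiving at least ``threshold``.

    ``threshold`` is in Gy, unless ``percent_of`` (a prescription in Gy) is
    given, in which case ``threshold`` is a percentage of it — e.g.
    ``dvh_V(c, 95, percent_of=74)`` is V95% against a 74 Gy prescription.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t = threshold / 100.0 * percent_of if percent_of is not None else threshold
    if t <= curve.dose_gy[0]:
        return 100.0
    if t >= curve.dose_gy[-1]:
        return float(curve.volume_fraction[-1] * 100.0)
    return float(np.interp(t, curve.dose_gy, curve.volume_fraction) * 100.0)


def _margin_footprint(
    margins: MarginSpec, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Voxel-offset footprint of the anisotropic margin.

    An offset (dz, dy, dx) is inside the expansion iff the per-octant
    ellipsoid inequality sum((offset_mm / directional margin)^2) <= 1 holds,
    the directional margin per axis being chosen by the sign of the offset
    component. A zero margin pins that half-axis to zero offset.
    """
    sz, sy, sx = spacing
    per_axis = (  # (negative-direction margin, positive-direction margin)
        (margins.inferior, margins.superior),   # z
        (margins.anterior, margins.posterior),  # y: +y posterior
        (margins.right, margins.left),          # x: +x patient-left
    )
    half = [
        int(np.floor(max(neg, pos) / sp + 1e-9))
        for (neg, pos), sp in zip(per_axis, spacing)
    ]
    offs = [np.arange(-h, h + 1) for h in half]
    dz, dy, dx = np.meshgrid(*offs, indexing="ij")
    total = np.zeros(dz.shape)
    for delta, sp, (neg, pos) in zip((dz, dy, dx), spacing, per_axis):
        mm = delta * sp
        m = np.where(mm >= 0, pos, neg)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(mm == 0, 0.0, (mm / m) ** 2)
        term = np.where((mm != 0) & (m == 0), np.inf, term)
        total += term
    return total <= 1.0 + 1e-12


def expand_margin(mask: BinaryMask3D, margins: MarginSpec) -> BinaryMask3D:
    """Expand a structure by anisotropic per-direction margins (CTV→PTV).

    A voxel joins the expansion iff it lies within the per-octant ellipsoidal
    distance bound of some structure voxel; the output is always a superset
    of the input. Expansion beyond the grid is clipped with a warning.
    """
    if mask.is_empty():
        raise ValueError("cannot expand an empty mask")
    foot = _margin_footprint(margins, mask.spacing)
    out = ndimage.binary_dilation(mask.values, structure=foot)
    # would the expansion have spilled past the grid?
    edge = np.zeros_like(out)
    edge[0], edge[-1] = True, True
    edge[:, 0], edge[:, -1] = True, True
    edge[:, :, 0], edge[:, :, -1] = True, True
    if bool((out & edge).any()):
        warnings.warn("margin expansion reaches the grid edge; result is clipped")
    return BinaryMask3D(out, mask.spacing, mask.origin)


def paddick_ci(
    target: BinaryMask3D,
    dose: DoseGrid,
    prescription: float,
    isodose_pct: float = 95.0,
) -> float:
    """Paddick conformity index ``TV_PIV^2 / (TV * PIV)``.

    PIV is the volume enclosed by the ``isodose_pct`` % prescription isodose,
    TV the target volume and TV_PIV their intersection; 1 is ideal. Returns
    0 with a warning when the isodose encloses no voxel.
    """
    target.require_same_geometry(dose, "paddick_ci")
    if target.is_empty():
        raise ValueError("Paddick CI needs a non-empty target")
    level = isodose_pct / 100.0 * prescription
    piv = dose.values >= level
    n_piv = int(piv.sum())
    if n_piv == 0:
        warnings.warn("prescription isodose encloses no voxel; CI set to 0")
        return 0.0
    tv = target.voxel_count
    tv_piv = int(np.count_nonzero(piv & target.values))
    return tv_piv**2 / (tv * n_piv)


@dataclasses.dataclass
class ICRU83Result:
    """PTV coverage check: D98% >= 95% and D2% <= 107% of prescription."""

    d98_gy: float
    d2_gy: float
    prescription: float
    d98_ok: bool
    d2_ok: bool
    d98_margin_gy: float  # positive = passes with room to spare
    d2_margin_gy: float

    @property
    def passed(self) -> bool:
        return self.d98_ok and self.d2_ok


def icru83_check(curve: DVHCurve, prescription: float) -> ICRU83Result:
    """Evaluate the ICRU Report 83 PTV coverage criteria on a DVH."""
    d98 = dvh_D(curve, 98)
    d2 = dvh_D(curve, 2)
    lo = 0.95 * prescription
    hi = 1.07 * prescription
    return ICRU83Result(
        d98_gy=d98,
        d2_gy=d2,
        prescription=prescription,
        d98_ok=d98 >= lo,
        d2_ok=d2 <= hi,
        d98_margin_gy=d98 - lo,
        d2_margin_gy=hi - d2,
    )
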