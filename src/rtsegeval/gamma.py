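"""3D global gamma analysis with a low-dose cut-off.

For every reference voxel whose dose is at least ``cutoff`` percent of the
prescription, the gamma index is

    gamma(x) = min over search offsets r of
               sqrt( |r|^2 / dta^2  +  (D_eval(x + r) - D_ref(x))^2 / dD^2 )

with a *global* dose normalization dD equal to ``dose_tolerance`` percent of
the prescription. A voxel passes when gamma <= 1; the pass rate is the
percentage of considered voxels that pass.

The search interpolates the evaluated dose trilinearly on a lattice refined
by ``subdivisions`` per axis (default 3, i.e. steps of one third of a voxel)
and visits offsets shell by shell in order of increasing physical length.
A voxel's search stops as soon as the shell radius alone exceeds its current
best gamma times dta — beyond that no offset can improve the minimum — which
makes the result exact on the refined lattice without a fixed search-radius
cap. Offsets falling outside the evaluated grid are skipped.

The metric is asymmetric: gamma(ref, eval) != gamma(eval, ref) in general.
The reference is the dose computed on the ground-truth contours.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grids import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_index"]

# pass threshold with float32 headroom: a voxel passes when gamma <= 1 up to
# single-precision rounding of the interpolated dose terms
_PASS_TOL = 1.0 + 1e-5


@dataclasses.dataclass
class GammaCriteria:
    """Tolerances of the gamma test, anchored to the prescription dose."""

    prescription: float
    dose_tolerance_pct: float = 3.0
    distance_tolerance_mm: float = 3.0
    cutoff_pct: float = 10.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


@dataclasses.dataclass
class GammaResult:
    """Per-voxel gamma map (NaN below cut-off) and the summary pass rate."""

    gamma_map: np.ndarray
    considered: np.ndarray
    pass_rate_pct: float
    n_considered: int
    n_passed: int


def _upsample_axis(a: np.ndarray, f: int, axis: int) -> np.ndarray:
    """Linear upsampling along one axis: n points -> (n-1)*f + 1 points."""
    if f == 1:
        return a
    a = np.moveaxis(a, axis, 0)
    n = a.shape[0]
    out = np.empty(((n - 1) * f + 1,) + a.shape[1:], dtype=np.float32)
    out[::f] = a
    for j in range(1, f):
        w = j / f
        out[j::f] = (1.0 - w) * a[:-1] + w * a[1:]
    return np.moveaxis(out, 0, axis)


def _offset_table(
    spacing: tuple[float, float, float],
    f: int,
    r_min: float,
    r_max: float,
    max_half: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Integer fine-lattice offsets with physical length in (r_min, r_max],
    sorted by length. ``max_half`` bounds each component by the grid size."""
    steps = np.asarray(spacing) / f
    half = [min(int(np.floor(r_max / s)), m) for s, m in zip(steps, max_half)]
    axes = [np.arange(-h, h + 1, dtype=np.int32) for h in half]
    dz, dy, dx = np.meshgrid(*axes, indexing="ij", copy=False)
    r2 = (
        (dz.astype(np.float32) * steps[0]) ** 2
        + (dy.astype(np.float32) * steps[1]) ** 2
        + (dx.astype(np.float32) * steps[2]) ** 2
    )
    r = np.sqrt(r2, out=r2)
    keep = (r > r_min) & (r <= r_max)
    offs = np.stack([dz[keep], dy[keep], dx[keep]], axis=1)
    r = r[keep]
    order = np.argsort(r, kind="stable")
    return offs[order], r[order]


def gamma_index(
    ref: DoseGrid,
    ev: DoseGrid,
    criteria: GammaCriteria,
    subdivisions: int = 3,
    chunk_elems: int = 4_000_000,
    exact_map: bool = False,
) -> GammaResult:
    """Global 3%/3 mm-style gamma comparison of ``ev`` against ``ref``.

    ``ev`` is resampled onto the reference lattice first if the geometries
    differ. ``subdivisions`` is the per-axis refinement of the distance
    search (search step = spacing / subdivisions).

    By default the search is confined to what the pass/fail decision needs:
    a voxel stops as soon as some offset brings its gamma to <= 1 (it is
    known to pass), and the search ball is capped at the distance tolerance
    — beyond |r| = dta the distance term alone exceeds 1, so no offset out
    there can make a voxel pass. Map entries are therefore exact for the
    decision but upper bounds on the true minimum for failing voxels.
    Pass/fail and the pass rate are unaffected. Set ``exact_map=True`` to
    refine every voxel to the exact minimum on the search lattice, with the
    search radius extended adaptively.
    """
    if not ref.same_geometry(ev):
        from .io import resample_to_grid

        ev = resample_to_grid(ev, like=ref)  # type: ignore[assignment]
    dta = criteria.distance_tolerance_mm
    dd = criteria.dose_tolerance_pct / 100.0 * criteria.prescription
    cutoff = criteria.cutoff_pct / 100.0 * criteria.prescription

    considered = ref.values >= cutoff
    n_cons = int(considered.sum())
    if n_cons == 0:
        raise ValueError(
            f"no reference voxel at or above the {criteria.cutoff_pct:g}% "
            f"dose cut-off ({cutoff:.2f} Gy)"
        )

    f = int(subdivisions)
    fine = ev.values.astype(np.float32)
    for ax in range(3):
        fine = _upsample_axis(fine, f, ax)
    fshape = np.asarray(fine.shape)

    idx = np.argwhere(considered)
    base = (idx * f).astype(np.int32)  # reference voxels on the fine lattice
    dref = ref.values[considered].astype(np.float32)

    # start from the zero offset
    min_g2 = ((fine[base[:, 0], base[:, 1], base[:, 2]] - dref) / dd) ** 2
    min_g2 = min_g2.astype(np.float64)
    active = np.arange(n_cons)

    max_half = tuple(int(s) - 1 for s in fshape)
    diag = float(np.sqrt((((fshape - 1) * np.asarray(ref.spacing) / f) ** 2).sum()))
    # a step of spacing/f can overshoot dta by less than one step; include it
    limit = diag if exact_map else min(diag, dta + max(ref.spacing) / f)
    r_done = 0.0
    r_target = min(1.5 * dta, limit) if limit > 0 else 0.0

    while active.size:
        # retire voxels that cannot improve beyond the searched radius —
        # and, unless an exact map is requested, voxels already passing
        keep = min_g2[active] > (r_done / dta) ** 2
        if not exact_map:
            keep &= min_g2[active] > _PASS_TOL**2
        active = active[keep]
        if not active.size or r_done >= limit:
            break
        offs, radii = _offset_table(
            ref.spacing, f, r_done, r_target, max_half
        )
        pos = 0
        while pos < len(offs) and active.size:
            m = max(1, min(len(offs) - pos, chunk_elems // max(active.size, 1)))
            o = offs[pos : pos + m]
            r = radii[pos : pos + m]
            keep = min_g2[active] > (r[0] / dta) ** 2
            if not exact_map:
                keep &= min_g2[active] > _PASS_TOL**2
            active = active[keep]
            if not active.size:
                break
            g2 = np.broadcast_to(
                ((r / dta) ** 2)[None, :], (active.size, o.shape[0])
            ).copy()
            de = None
            valid_all = True
            coords = []
            for ax in range(3):
                p = base[active, ax][:, None] + o[None, :, ax]
                bad = (p < 0) | (p >= fshape[ax])
                if bad.any():
                    np.clip(p, 0, fshape[ax] - 1, out=p)
                    g2[bad] = np.inf
                    valid_all = False
                coords.append(p)
            de = fine[coords[0], coords[1], coords[2]]
            de -= dref[active, None]
            de /= dd
            if valid_all:
                g2 += de * de
            else:
                finite = np.isfinite(g2)
                g2[finite] += (de * de)[finite]
            min_g2[active] = np.minimum(min_g2[active], g2.min(axis=1))
            pos += m
        r_done = r_target
        if active.size:
            needed = dta * float(np.sqrt(min_g2[active].max()))
            # geometric growth: avoid building one huge offset table when
            # only a handful of hard voxels remain
            r_target = min(needed, max(r_done * 1.5, r_done + dta), limit)
            if r_target <= r_done:
                break

    gamma = np.sqrt(min_g2)
    gmap = np.full(ref.shape, np.nan)
    gmap[considered] = gamma
    n_pass = int(np.count_nonzero(gamma <= _PASS_TOL))
    return GammaResult(
        gamma_map=gmap,
        considered=considered,
        pass_rate_pct=100.0 * n_pass / n_cons,
        n_considered=n_cons,
        n_passed=n_pass,
    )
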