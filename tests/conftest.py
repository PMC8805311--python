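import numpy as np
import pytest
from scipy import ndimage

from rtsegeval.grids import BinaryMask3D, DoseGrid


def ball_mask(radius_mm, shape=(48, 48, 48), spacing=(1.0, 1.0, 1.0), center=None):
    """Digital ball: voxel centers within radius_mm of the center."""
    if center is None:
        center = tuple((s - 1) / 2.0 * sp for s, sp in zip(shape, spacing))
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij", sparse=True
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return BinaryMask3D(d2 <= radius_mm**2, spacing, (0.0, 0.0, 0.0))


def random_blob_mask(rng, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0)):
    """Random connected-ish mask: thresholded smoothed noise, non-empty."""
    while True:
        field = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
        mask = field > np.percentile(field, 75)
        if mask.any():
            return BinaryMask3D(mask, spacing, (0.0, 0.0, 0.0))


def smooth_dose_pair(rng, shape=(14, 14, 14), prescription=74.0, noise_frac=0.04):
    """A smooth reference dose and a smoothly perturbed evaluated dose."""
    base = ndimage.gaussian_filter(rng.normal(size=shape), 2.5)
    base = (base - base.min()) / np.ptp(base)
    ref = prescription * (0.05 + 1.03 * base)
    delta = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    delta *= noise_frac * prescription / max(delta.std(), 1e-9)
    ev = np.clip(ref + delta, 0.0, None)
    return DoseGrid(ref), DoseGrid(ev)


def gamma_pass_oracle_fast(ref, ev, crit, step_mm=0.1):
    """Exhaustive pass/fail gamma oracle on a ``step_mm`` search lattice.

    A voxel can only pass within distance dta of itself (the distance term
    alone exceeds 1 beyond), so scanning all fine-lattice offsets with
    |r| <= dta is exhaustive for the pass/fail decision. Offsets are visited
    in order of increasing length and voxels leave the undecided set as soon
    as a passing offset is found; failing voxels scan the full ball.
    Returns (passed, considered) boolean volumes.
    """
    from scipy.interpolate import RegularGridInterpolator

    assert ref.spacing == (1.0, 1.0, 1.0), "oracle assumes 1 mm grids"
    f = round(1.0 / step_mm)
    dta = crit.distance_tolerance_mm
    dd = crit.dose_tolerance_pct / 100 * crit.prescription
    cutoff = crit.cutoff_pct / 100 * crit.prescription

    axes = [np.arange(n) for n in ev.shape]
    interp = RegularGridInterpolator(axes, ev.values)
    fine_axes = [np.arange(0, (n - 1) * f + 1) / f for n in ev.shape]
    mesh = np.meshgrid(*fine_axes, indexing="ij")
    fine = interp(np.stack([m.ravel() for m in mesh], axis=1)).reshape(
        [len(a) for a in fine_axes]
    )
    fshape = np.asarray(fine.shape)

    h = int(np.floor(dta * f))
    offs = np.stack(
        np.meshgrid(*(np.arange(-h, h + 1),) * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    r = np.linalg.norm(offs / f, axis=1)
    inside = r <= dta
    offs, r = offs[inside], r[inside]
    order = np.argsort(r)
    offs, r = offs[order], r[order]
    dist2 = (r / dta) ** 2

    considered = ref.values >= cutoff
    vox = np.argwhere(considered)
    base = vox * f
    dref = ref.values[considered]
    passed_flat = np.zeros(len(vox), dtype=bool)
    undecided = np.arange(len(vox))
    chunk = 2000
    pos = 0
    while pos < len(offs) and undecided.size:
        o = offs[pos : pos + chunk]
        d2 = dist2[pos : pos + chunk]
        p = base[undecided][:, None, :] + o[None, :, :]
        ok = np.all((p >= 0) & (p < fshape), axis=2)
        pc = np.clip(p, 0, fshape - 1)
        de = fine[pc[..., 0], pc[..., 1], pc[..., 2]]
        g2 = d2[None, :] + ((de - dref[undecided, None]) / dd) ** 2
        g2 = np.where(ok, g2, np.inf)
        hit = (g2 <= 1.0).any(axis=1)
        passed_flat[undecided[hit]] = True
        undecided = undecided[~hit]
        pos += chunk
    passed = np.zeros(ref.shape, dtype=bool)
    passed[considered] = passed_flat
    return passed, considered


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
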