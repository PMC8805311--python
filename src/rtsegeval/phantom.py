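"""Synthetic pelvic phantoms, perturbed contours and surrogate dose grids.

The phantom stands in for the clinical cohort: a prostate (ellipsoid), a
bladder (ellipsoid, superior-anterior) and a rectum (curved posterior tube)
on a 1 mm lattice, from which the evaluation pipeline's inputs are built.
Perturbed masks play the role of auto-segmented contours; they are drawn
from the same augmentation family used to train segmentation networks on
such data (rotations, translations, per-axis zoom, smooth grid-based
deformation, each applied with a configurable probability). The surrogate
dose model replaces a treatment planning system: prescription dose inside
the PTV and an exponential fall-off with distance from the PTV surface,
reaching about 10% of the prescription one fall-off length away on the
10-per-decade scale.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .dosimetry import MarginSpec, expand_margin
from .grids import BinaryMask3D, DoseGrid, Image3D

__all__ = [
    "PhantomSpec",
    "PerturbationParams",
    "DoseSurrogateSpec",
    "SimCase",
    "generate_phantom",
    "perturb_mask",
    "generate_surrogate_dose",
    "generate_cohort",
]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and intensity model of the synthetic pelvis.

    Organ positions are given relative to the prostate center, which sits at
    the grid center. Axis order is ``(z, y, x)`` with +z superior and +y
    posterior; semi-axes and offsets are in mm. Intensities are HU-like and
    clamped to ``intensity_window`` after adding Gaussian noise.
    """

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    prostate_semi_axes: tuple[float, float, float] = (17.0, 20.0, 22.0)
    bladder_semi_axes: tuple[float, float, float] = (24.0, 26.0, 28.0)
    bladder_offset: tuple[float, float, float] = (36.0, -32.0, 0.0)
    rectum_radius: float = 11.0
    rectum_length: float = 100.0
    rectum_offset_y: float = 34.0
    rectum_curve: float = 6.0
    background_intensity: float = -20.0
    organ_intensity: dict = dataclasses.field(
        default_factory=lambda: {"prostate": 40.0, "bladder": 20.0, "rectum": 25.0}
    )
    noise_sd: float = 10.0
    intensity_window: tuple[float, float] = (-150.0, 150.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(self.spacing)


@dataclasses.dataclass
class PerturbationParams:
    """Parameters of the contour-perturbation family.

    Defaults mirror the augmentation settings such networks are trained
    with: rotations up to 20°/10°/10° about the SI/AP/ML axes, translations
    up to 10 mm per axis, per-axis zoom in [0.9, 1.1], a 15³ control-point
    deformation grid, and application probability 0.93 per component.
    ``deform_sigma`` is the Gaussian control-point displacement in mm; the
    default of 3 mm keeps the perturbed contour anatomically plausible (one
    tenth of the raw training-augmentation setting, which is tuned for
    intensity-image augmentation rather than contour perturbation).
    """

    max_angles_deg: tuple[float, float, float] = (20.0, 10.0, 10.0)
    max_translation_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    zoom_range: tuple[float, float] = (0.9, 1.1)
    deform_grid_n: int = 15
    deform_mu: float = 0.0
    deform_sigma: float = 3.0
    p_apply: float = 0.93
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.zoom_range
        if not (lo <= 1.0 <= hi) or lo <= 0:
            raise ValueError("zoom_range must bracket 1 with a positive lower bound")
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")
        if self.deform_grid_n < 2:
            raise ValueError("deform_grid_n must be >= 2")


@dataclasses.dataclass
class DoseSurrogateSpec:
    """Surrogate conformal dose model around a PTV.

    ``falloff_length`` is the distance (mm) over which the dose outside the
    PTV drops by a factor of 10 — i.e. to 10% of the prescription one
    fall-off length from the PTV surface, matching the ~1 cm low-dose
    fall-off objective of a VMAT prostate plan. ``plateau_noise_sd`` adds
    smooth within-PTV heterogeneity (Gy).
    """

    prescription: float = 74.0
    fractions: int = 37
    falloff_length: float = 10.0
    plateau_noise_sd: float = 0.5
    background_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.prescription <= 0 or self.falloff_length <= 0:
            raise ValueError("prescription and falloff_length must be positive")
        if not 0 <= self.background_fraction < 0.1:
            raise ValueError("background_fraction must be in [0, 0.1)")


def _coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(
        *(np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)),
        indexing="ij",
        sparse=True,
    )


def _check_inside(name: str, lo: np.ndarray, hi: np.ndarray, spec: PhantomSpec) -> None:
    extent = (np.asarray(spec.grid_shape) - 1) * np.asarray(spec.spacing)
    if np.any(lo < 0) or np.any(hi > extent):
        raise ValueError(
            f"{name} extends outside the grid: bounds [{lo}, {hi}] mm vs "
            f"grid extent [0, {extent}] mm"
        )


def generate_phantom(
    spec: PhantomSpec, seed: int = 0
) -> tuple[Image3D, dict[str, BinaryMask3D]]:
    """Build the phantom image and its ground-truth organ masks.

    Raises when an organ's analytic bounds exceed the grid or when any two
    organ masks overlap. Deterministic given ``(spec, seed)``.
    """
    zz, yy, xx = _coords_mm(spec)
    cz, cy, cx = spec.center_mm

    pa = np.asarray(spec.prostate_semi_axes)
    _check_inside("prostate", spec.center_mm - pa, spec.center_mm + pa, spec)
    prostate = (
        ((zz - cz) / pa[0]) ** 2 + ((yy - cy) / pa[1]) ** 2 + ((xx - cx) / pa[2]) ** 2
    ) <= 1.0

    bc = spec.center_mm + np.asarray(spec.bladder_offset)
    ba = np.asarray(spec.bladder_semi_axes)
    _check_inside("bladder", bc - ba, bc + ba, spec)
    bladder = (
        ((zz - bc[0]) / ba[0]) ** 2
        + ((yy - bc[1]) / ba[1]) ** 2
        + ((xx - bc[2]) / ba[2]) ** 2
    ) <= 1.0

    half_len = spec.rectum_length / 2.0
    r, curve, y0 = spec.rectum_radius, spec.rectum_curve, spec.rectum_offset_y
    lo = np.array([cz - half_len, cy + y0 - r, cx - r])
    hi = np.array([cz + half_len, cy + y0 + 2 * curve + r, cx + r])
    _check_inside("rectum", lo, hi, spec)
    # centerline bows posterior away from the prostate plane at mid-height
    ycl = cy + y0 + curve * (1.0 - np.cos(np.pi * (zz - cz) / spec.rectum_length))
    rectum = (
        (np.abs(zz - cz) <= half_len)
        & (((yy - ycl) ** 2 + (xx - cx) ** 2) <= r**2)
    )

    masks = {"prostate": prostate, "bladder": bladder, "rectum": rectum}
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if bool((masks[a] & masks[b]).any()):
                raise ValueError(f"organ masks {a!r} and {b!r} overlap")

    img = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    for name, m in masks.items():
        img[m] = spec.organ_intensity[name]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    img = np.clip(img, *spec.intensity_window)

    image = Image3D(img, spec.spacing)
    out = {
        name: BinaryMask3D(m, spec.spacing) for name, m in masks.items()
    }
    return image, out


def _rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation about the SI (z), AP (y) and ML (x) axes, in (z, y, x) order."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    # matrices act on (z, y, x) mm vectors
    rz = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])  # about z: mixes (y, x)
    ry = np.array([[cb, 0, -sb], [0, 1, 0], [sb, 0, cb]])  # about y: mixes (z, x)
    rx = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])  # about x: mixes (z, y)
    return rz @ ry @ rx


def perturb_mask(mask: BinaryMask3D, params: PerturbationParams) -> BinaryMask3D:
    """Apply the perturbation family to a mask, emulating auto-segmentation.

    Components are composed as zoom → rotation → translation → deformation,
    each switched on independently with probability ``p_apply``; resampling
    is nearest-neighbour about the grid center, so the output stays binary.
    Deterministic given ``params.seed``; raises if the perturbed structure
    leaves the grid entirely.
    """
    if mask.is_empty():
        raise ValueError("cannot perturb an empty mask")
    rng = np.random.default_rng(params.seed)
    apply = rng.random(4) < params.p_apply
    angles = np.deg2rad(rng.uniform(-1, 1, 3) * np.asarray(params.max_angles_deg))
    shifts = rng.uniform(-1, 1, 3) * np.asarray(params.max_translation_mm)
    zoom = rng.uniform(*params.zoom_range, size=3)
    n = params.deform_grid_n
    ctrl = rng.normal(params.deform_mu, params.deform_sigma, size=(3, n, n, n))

    if not apply[0]:
        zoom = np.ones(3)
    if not apply[1]:
        angles = np.zeros(3)
    if not apply[2]:
        shifts = np.zeros(3)

    spacing = np.asarray(mask.spacing)
    shape = np.asarray(mask.shape)
    center = (shape - 1) / 2.0 * spacing
    fwd = _rotation_matrix(*angles) @ np.diag(zoom)  # zoom, then rotation
    inv = np.linalg.inv(fwd)
    use_deform = bool(apply[3]) and params.deform_sigma > 0

    # forward-transform the input bounding box to find where the output can
    # be non-zero; restrict all work to that block (plus a deformation pad)
    occ = np.argwhere(mask.values)
    corners_idx = np.array(
        [[occ[:, a].min() if bit & (1 << a) else occ[:, a].max() for a in range(3)]
         for bit in range(8)]
    )
    corners_mm = corners_idx * spacing
    out_mm = (fwd @ (corners_mm - center).T).T + center + shifts
    pad = (abs(params.deform_mu) + 4 * params.deform_sigma if use_deform else 0.0)
    lo = np.floor((out_mm.min(axis=0) - pad) / spacing).astype(int) - 1
    hi = np.ceil((out_mm.max(axis=0) + pad) / spacing).astype(int) + 2
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, shape)
    if np.any(lo >= hi):
        raise ValueError(
            "perturbation moved the structure entirely off the grid "
            f"(angles={np.rad2deg(angles)}, shifts={shifts}, zoom={zoom})"
        )
    bshape = tuple(hi - lo)
    axes_mm = [
        ((np.arange(l, h) * s).astype(np.float32))
        for l, h, s in zip(lo, hi, spacing)
    ]
    grids = np.meshgrid(*axes_mm, indexing="ij", sparse=True)
    pre = []  # output mm coords, plus backward deformation displacement
    if use_deform:
        scale = (np.asarray([n - 1] * 3)) / np.maximum(shape - 1, 1)
        ctrl_coords = [
            (np.arange(l, h) * sc).astype(np.float32)
            for l, h, sc in zip(lo, hi, scale)
        ]
        cz, cy, cx = np.meshgrid(*ctrl_coords, indexing="ij")
        cpts = np.stack([cz, cy, cx]).reshape(3, -1)
        for ax in range(3):
            disp = ndimage.map_coordinates(
                ctrl[ax], cpts, order=3, mode="nearest"
            ).reshape(bshape)
            pre.append(grids[ax] + disp)
        del cz, cy, cx, cpts
    else:
        pre = [np.broadcast_to(g, bshape) for g in grids]
    src_idx = np.empty((3,) + bshape, dtype=np.float32)
    for a in range(3):
        acc = np.full(bshape, center[a], dtype=np.float32)
        for b in range(3):
            acc += inv[a, b] * (pre[b] - np.float32(center[b] + shifts[b]))
        src_idx[a] = acc / np.float32(spacing[a])
    block = ndimage.map_coordinates(
        mask.values.astype(np.uint8), src_idx, order=0
    ).astype(bool)
    out = np.zeros(mask.shape, dtype=bool)
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = block
    if not out.any():
        raise ValueError(
            "perturbation moved the structure entirely off the grid "
            f"(angles={np.rad2deg(angles)}, shifts={shifts}, zoom={zoom})"
        )
    return BinaryMask3D(out, mask.spacing, mask.origin)



def generate_surrogate_dose(
    ptv: BinaryMask3D, spec: DoseSurrogateSpec, seed: int = 0
) -> DoseGrid:
    """Conformal surrogate dose: prescription on the PTV, exponential fall-off.

    Outside the PTV the dose decays by one decade per ``falloff_length`` of
    Euclidean distance from the PTV surface, floored at
    ``background_fraction`` of the prescription (the low-dose bath). Smooth
    plateau noise (zero mean, ``plateau_noise_sd`` Gy) is added inside the
    PTV only, so the radial monotone decrease outside is preserved.
    """
    if ptv.is_empty():
        raise ValueError("cannot build a dose distribution for an empty PTV")
    dist = ndimage.distance_transform_edt(~ptv.values, sampling=ptv.spacing)
    rx = spec.prescription
    frac = spec.background_fraction + (1.0 - spec.background_fraction) * np.power(
        10.0, -dist / spec.falloff_length
    )
    dose = rx * frac
    dose[ptv.values] = rx
    if spec.plateau_noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, 1.0, size=ptv.shape)
        sigma_vox = [5.0 / s for s in ptv.spacing]  # 5 mm correlation length
        noise = ndimage.gaussian_filter(noise, sigma_vox)
        sd = noise.std()
        if sd > 0:
            noise *= spec.plateau_noise_sd / sd
        dose[ptv.values] += noise[ptv.values]
    return DoseGrid(np.maximum(dose, 0.0), ptv.spacing, ptv.origin)


@dataclasses.dataclass
class SimCase:
    """One simulated evaluation case: anatomy, contours and both dose grids."""

    case_id: str
    image: Image3D
    gt_masks: dict[str, BinaryMask3D]
    pred_masks: dict[str, BinaryMask3D]
    dose_ref: DoseGrid | None  # plan optimized on the ground-truth PTV
    dose_test: DoseGrid | None  # plan optimized on the perturbed (predicted) PTV
    seed: int


def generate_cohort(
    n_cases: int,
    spec: PhantomSpec | None = None,
    params: PerturbationParams | None = None,
    dose_spec: DoseSurrogateSpec | None = None,
    seed: int = 0,
    margins: MarginSpec | None = None,
    crop_size: tuple[int, int, int] | None = (128, 128, 128),
    generate_doses: bool = True,
) -> list[SimCase]:
    """Simulate a cohort of cases with perturbed contours and paired doses.

    Each case derives its own random stream from the root ``seed``. Both
    dose grids of a case share the same plateau-noise stream, so with
    zero-magnitude perturbations the two grids are identical — mirroring a
    planning system re-run on the same contours with fixed settings. All
    volumes are cropped to ``crop_size`` (default 128³) around the
    ground-truth prostate center of mass. ``generate_doses=False`` skips the
    dose grids (both set to None) for purely geometric studies.
    """
    from .io import crop_centered

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    spec = spec or PhantomSpec()
    params = params or PerturbationParams()
    dose_spec = dose_spec or DoseSurrogateSpec()
    margins = margins or MarginSpec()

    streams = np.random.SeedSequence(seed).spawn(n_cases)
    cases = []
    for i, ss in enumerate(streams):
        s_phantom, s_perturb, s_dose = (
            int(v) for v in ss.generate_state(3) % (2**31)
        )
        image, gt = generate_phantom(spec, seed=s_phantom)
        pred = {}
        for j, (name, m) in enumerate(gt.items()):
            p = dataclasses.replace(params, seed=s_perturb + j)
            pred[name] = perturb_mask(m, p)
        if crop_size is not None:
            com = image.index_to_mm(
                np.asarray(ndimage.center_of_mass(gt["prostate"].values))
            )
            image = crop_centered(image, tuple(com), crop_size)
            gt = {k: crop_centered(v, tuple(com), crop_size) for k, v in gt.items()}
            pred = {k: crop_centered(v, tuple(com), crop_size) for k, v in pred.items()}
        dose_ref = dose_test = None
        if generate_doses:
            ptv_gt = expand_margin(gt["prostate"], margins)
            ptv_pred = expand_margin(pred["prostate"], margins)
            dose_ref = generate_surrogate_dose(ptv_gt, dose_spec, seed=s_dose)
            dose_test = generate_surrogate_dose(ptv_pred, dose_spec, seed=s_dose)
        cases.append(
            SimCase(
                case_id=f"case{i:02d}",
                image=image,
                gt_masks=gt,
                pred_masks=pred,
                dose_ref=dose_ref,
                dose_test=dose_test,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
        )
    return cases
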