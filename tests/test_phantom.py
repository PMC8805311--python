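"""Phantom, perturbation and surrogate-dose generators: contracts and oracles."""

import dataclasses

import numpy as np
import pytest

from rtsegeval.dosimetry import MarginSpec
from rtsegeval.geometry import dsc
from rtsegeval.grids import BinaryMask3D
from rtsegeval.phantom import (
    DoseSurrogateSpec,
    PerturbationParams,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_surrogate_dose,
    perturb_mask,
)

from conftest import ball_mask

SMALL = PhantomSpec(grid_shape=(128, 128, 128), noise_sd=0.0)

# compact anatomy that fits a 96^3 grid, for cheaper end-to-end checks
COMPACT = PhantomSpec(
    grid_shape=(96, 96, 96),
    noise_sd=0.0,
    bladder_offset=(30.0, -26.0, 0.0),
    bladder_semi_axes=(16.0, 18.0, 20.0),
    rectum_length=60.0,
    rectum_radius=8.0,
    rectum_curve=2.0,
)

IDENTITY = PerturbationParams(
    max_angles_deg=(0, 0, 0),
    max_translation_mm=(0, 0, 0),
    zoom_range=(1, 1),
    deform_sigma=0.0,
    seed=0,
)


class TestGeneratePhantom:
    def test_spherical_prostate_volume_matches_analytic(self):
        spec = dataclasses.replace(SMALL, prostate_semi_axes=(20.0, 20.0, 20.0))
        _, masks = generate_phantom(spec, seed=0)
        analytic = 4.0 / 3.0 * np.pi * 20.0**3
        assert masks["prostate"].volume_mm3 == pytest.approx(analytic, rel=0.02)

    def test_deterministic_given_seed(self):
        spec = PhantomSpec()
        i1, m1 = generate_phantom(spec, seed=42)
        i2, m2 = generate_phantom(spec, seed=42)
        np.testing.assert_array_equal(i1.values, i2.values)
        for k in m1:
            np.testing.assert_array_equal(m1[k].values, m2[k].values)

    def test_no_noise_image_takes_configured_values_only(self):
        img, _ = generate_phantom(SMALL, seed=0)
        expected = {
            SMALL.background_intensity,
            *SMALL.organ_intensity.values(),
        }
        assert set(np.unique(img.values)) <= expected

    def test_masks_pairwise_disjoint_and_inside(self):
        _, masks = generate_phantom(PhantomSpec(), seed=3)
        names = list(masks)
        for i, a in enumerate(names):
            assert masks[a].voxel_count > 0
            for b in names[i + 1 :]:
                assert not (masks[a].values & masks[b].values).any()

    def test_organ_exceeding_grid_rejected(self):
        spec = dataclasses.replace(SMALL, bladder_offset=(90.0, -32.0, 0.0))
        with pytest.raises(ValueError, match="bladder"):
            generate_phantom(spec, seed=0)


class TestPerturbMask:
    def test_zero_magnitudes_identity(self):
        _, masks = generate_phantom(SMALL, seed=0)
        out = perturb_mask(masks["prostate"], IDENTITY)
        np.testing.assert_array_equal(out.values, masks["prostate"].values)

    def test_deterministic_given_seed(self):
        _, masks = generate_phantom(SMALL, seed=0)
        p = PerturbationParams(seed=123)
        a = perturb_mask(masks["prostate"], p)
        b = perturb_mask(masks["prostate"], p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_output_stays_binary_and_nonempty(self):
        _, masks = generate_phantom(SMALL, seed=0)
        out = perturb_mask(masks["rectum"], PerturbationParams(seed=5))
        assert out.values.dtype == bool
        assert out.voxel_count > 0

    def test_pure_translation_matches_sphere_overlap_formula(self):
        # DSC of a radius-r ball and its copy shifted by d:
        # 1 - 3d/(4r) + d^3/(16 r^3)
        r, d = 20.0, 3.0
        ball = ball_mask(r, shape=(64, 64, 64))
        shifted = BinaryMask3D(np.roll(ball.values, int(d), axis=0), ball.spacing)
        expected = 1 - 3 * d / (4 * r) + d**3 / (16 * r**3)
        assert dsc(ball, shifted) == pytest.approx(expected, rel=0.02)
        # and the perturbation engine reproduces the same value for a fixed
        # translation (uniform draw with equal bounds collapses to +/-d)
        params = dataclasses.replace(IDENTITY, max_translation_mm=(d, 0, 0), p_apply=1.0)
        found = False
        for seed in range(8):
            out = perturb_mask(ball, dataclasses.replace(params, seed=seed))
            got = dsc(ball, out)
            # replicate the engine's draw order to recover the sampled shift
            rng = np.random.default_rng(seed)
            rng.random(4)  # per-component application draws
            rng.uniform(-1, 1, 3)  # rotation angles (zeroed by max_angles=0)
            shift = rng.uniform(-1, 1, 3)[0] * d
            analytic = 1 - 3 * abs(shift) / (4 * r) + abs(shift) ** 3 / (16 * r**3)
            assert got == pytest.approx(analytic, abs=0.02)
            found = True
        assert found

    def test_dsc_decreases_with_translation_magnitude_on_average(self):
        ball = ball_mask(15.0, shape=(72, 72, 72))
        means = []
        for d in (0.0, 3.0, 8.0):
            vals = []
            for seed in range(10):
                p = dataclasses.replace(
                    IDENTITY, max_translation_mm=(d, d, d), p_apply=1.0, seed=seed
                )
                vals.append(dsc(ball, perturb_mask(ball, p)))
            means.append(np.mean(vals))
        assert means[0] == 1.0
        assert means[0] > means[1] > means[2]

    def test_structure_pushed_off_grid_raises(self):
        small = ball_mask(2.0, shape=(10, 10, 10))
        p = dataclasses.replace(IDENTITY, max_translation_mm=(50, 0, 0), p_apply=1.0, seed=1)
        with pytest.raises(ValueError, match="off the grid"):
            perturb_mask(small, p)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            perturb_mask(BinaryMask3D(np.zeros((4, 4, 4), dtype=bool)), IDENTITY)


class TestSurrogateDose:
    def test_prescription_inside_ptv_when_noise_off(self):
        ptv = ball_mask(10.0, shape=(48, 48, 48))
        spec = DoseSurrogateSpec(plateau_noise_sd=0.0)
        dose = generate_surrogate_dose(ptv, spec, seed=0)
        np.testing.assert_allclose(dose.values[ptv.values], 74.0)

    def test_far_field_below_ten_percent(self):
        ptv = ball_mask(6.0, shape=(80, 80, 80))
        spec = DoseSurrogateSpec(plateau_noise_sd=0.0)
        dose = generate_surrogate_dose(ptv, spec, seed=0)
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~ptv.values)
        far = dist >= 3 * spec.falloff_length
        assert far.any()
        assert np.all(dose.values[far] < 0.10 * spec.prescription)

    def test_monotone_non_increasing_along_rays(self):
        ptv = ball_mask(8.0, shape=(64, 64, 64))
        dose = generate_surrogate_dose(ptv, DoseSurrogateSpec(plateau_noise_sd=0.0), 0)
        c = 31.5
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            ts = np.arange(0, 30, 0.5)
            pts = np.clip(np.rint(c + ts[:, None] * u).astype(int), 0, 63)
            vals = dose.values[pts[:, 0], pts[:, 1], pts[:, 2]]
            assert np.all(np.diff(vals) <= 1e-9)

    def test_deterministic_and_empty_ptv_rejected(self):
        ptv = ball_mask(5.0, shape=(24, 24, 24))
        d1 = generate_surrogate_dose(ptv, DoseSurrogateSpec(), seed=9)
        d2 = generate_surrogate_dose(ptv, DoseSurrogateSpec(), seed=9)
        np.testing.assert_array_equal(d1.values, d2.values)
        with pytest.raises(ValueError, match="empty PTV"):
            generate_surrogate_dose(
                BinaryMask3D(np.zeros((4, 4, 4), dtype=bool)), DoseSurrogateSpec(), 0
            )


class TestGenerateCohort:
    def test_reproducible_cases(self):
        k = dict(
            spec=COMPACT,
            params=PerturbationParams(max_translation_mm=(3, 3, 3),
                                      max_angles_deg=(5, 5, 5), deform_sigma=1.0),
            crop_size=(64, 64, 64),
            generate_doses=False,
        )
        c1 = generate_cohort(2, seed=7, **k)
        c2 = generate_cohort(2, seed=7, **k)
        assert len(c1) == 2
        for a, b in zip(c1, c2):
            for n in a.gt_masks:
                np.testing.assert_array_equal(a.gt_masks[n].values, b.gt_masks[n].values)
                np.testing.assert_array_equal(
                    a.pred_masks[n].values, b.pred_masks[n].values
                )

    def test_zero_perturbation_gives_identical_dose_grids(self):
        cases = generate_cohort(
            1, spec=COMPACT, params=IDENTITY, seed=3, crop_size=(80, 80, 80)
        )
        c = cases[0]
        np.testing.assert_array_equal(c.dose_ref.values, c.dose_test.values)
        for n in c.gt_masks:
            np.testing.assert_array_equal(c.gt_masks[n].values, c.pred_masks[n].values)
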