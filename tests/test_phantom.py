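"""Phantom geometry, seeding, ground-truth deformations and lesions."""

import numpy as np
import pytest

from ablaquant.elasticity import MaterialParams
from ablaquant.errors import GeometryError
from ablaquant.imaging_io import BLADDER, PROSTATE, RECTUM
from ablaquant.phantom import (PhantomFEM, PhantomSpec, calibrate_force_scale,
                               dice_after, embed_focal_lesion,
                               generate_phantom,
                               generate_synthetic_deformation)
from ablaquant.quantify import dice, organ_volume


class TestGeneratePhantom:
    def test_seeded_determinism(self, tiny_spec):
        img1, lab1 = generate_phantom(tiny_spec)
        img2, lab2 = generate_phantom(tiny_spec)
        assert np.array_equal(img1.data, img2.data)
        assert np.array_equal(lab1.labels, lab2.labels)

    def test_different_seeds_differ(self, tiny_spec):
        import dataclasses
        other = dataclasses.replace(tiny_spec, seed=tiny_spec.seed + 1)
        img1, _ = generate_phantom(tiny_spec)
        img2, _ = generate_phantom(other)
        assert not np.array_equal(img1.data, img2.data)

    def test_default_prostate_volume_matches_ellipsoid(self):
        # semi-axes (23,23,23) mm at 1 mm spacing: ~51 ml, the cohort median
        img, labels = generate_phantom(PhantomSpec())
        analytic_ml = 4.0 / 3.0 * np.pi * 23.0 ** 3 / 1000.0
        assert organ_volume(labels, PROSTATE) == pytest.approx(
            analytic_ml, rel=0.02)

    def test_zero_noise_piecewise_constant(self, tiny_spec):
        import dataclasses
        spec = dataclasses.replace(tiny_spec, noise_sd=0.0)
        img, labels = generate_phantom(spec)
        for lab in (PROSTATE, BLADDER, RECTUM):
            values = img.data[labels.labels == lab]
            assert np.all(values == values.flat[0])
        # background is piecewise constant too: tissue plus bone pillars
        bg = img.data[labels.labels == 0]
        assert set(np.unique(bg)) <= {spec.intensity_means[0],
                                      spec.bone_intensity}

    def test_overlapping_organs_rejected(self, tiny_spec):
        import dataclasses
        bad = dataclasses.replace(
            tiny_spec, bladder_center=tiny_spec.prostate_center)
        with pytest.raises(GeometryError, match="overlap"):
            generate_phantom(bad)

    def test_all_three_organs_present(self, tiny_phantom):
        _, labels = tiny_phantom
        for lab in (PROSTATE, BLADDER, RECTUM):
            assert labels.mask(lab).any()

    def test_organs_disjoint(self, compact_phantom):
        _, labels = compact_phantom
        total = sum(int(labels.mask(lab).sum())
                    for lab in (PROSTATE, BLADDER, RECTUM))
        assert total == int((labels.labels > 0).sum())


@pytest.fixture(scope="module")
def tiny_fem(tiny_phantom, soft_tissue):
    _, labels = tiny_phantom
    return PhantomFEM(labels, soft_tissue, element_mm=2.0, margin_mm=6.0)


class TestSyntheticDeformation:
    def test_zero_force_scale_gives_zero_field(self, tiny_phantom, tiny_fem):
        d = generate_synthetic_deformation(tiny_phantom, 0.0, seed=3,
                                           fem=tiny_fem)
        assert np.abs(d.field.vectors).max() == 0.0

    def test_field_linear_in_force_scale(self, tiny_phantom, tiny_fem):
        d1 = generate_synthetic_deformation(tiny_phantom, 1.0, seed=3,
                                            fem=tiny_fem)
        d2 = generate_synthetic_deformation(tiny_phantom, 2.0, seed=3,
                                            fem=tiny_fem)
        assert np.allclose(d2.field.vectors, 2.0 * d1.field.vectors,
                           atol=1e-8)

    def test_missing_organ_rejected(self, tiny_phantom):
        img, labels = tiny_phantom
        no_bladder = labels.copy_geometry(
            np.where(labels.labels == BLADDER, 0, labels.labels))
        with pytest.raises(GeometryError):
            generate_synthetic_deformation((img, no_bladder), 1.0, seed=0)

    def test_calibration_reaches_target_dice(self, tiny_phantom, tiny_fem):
        scale, deform, achieved = calibrate_force_scale(
            tiny_phantom, 0.75, tolerance=0.02, seed=5, fem=tiny_fem)
        _, labels = tiny_phantom
        re_eval = dice_after(labels, deform, scale)
        assert re_eval == pytest.approx(0.75, abs=0.02)

    def test_dice_monotone_in_scale(self, tiny_phantom, tiny_fem):
        scale, deform, _ = calibrate_force_scale(
            tiny_phantom, 0.75, tolerance=0.02, seed=5, fem=tiny_fem)
        _, labels = tiny_phantom
        dices = [dice_after(labels, deform, s)
                 for s in np.linspace(0.0, scale, 5)]
        assert dices[0] == pytest.approx(1.0)
        assert all(a >= b - 0.015 for a, b in zip(dices, dices[1:]))

    def test_trivial_target_dice_needs_no_force(self, tiny_phantom, tiny_fem):
        scale, _, _ = calibrate_force_scale(tiny_phantom, 0.999,
                                            tolerance=0.01, seed=5,
                                            fem=tiny_fem)
        assert scale < 0.5

    def test_invalid_target_rejected(self, tiny_phantom):
        with pytest.raises(ValueError):
            calibrate_force_scale(tiny_phantom, 1.5)


class TestFocalLesion:
    def test_null_lesion_is_identity(self, tiny_phantom, tiny_spec):
        img, labels = tiny_phantom
        out_img, out_lab, fld = embed_focal_lesion(
            tiny_phantom, tiny_spec.prostate_center, 0.0, 0.0)
        assert np.array_equal(out_lab.labels, labels.labels)
        assert np.array_equal(out_img.data, img.data)
        assert np.abs(fld.vectors).max() == 0.0

    def test_site_outside_prostate_rejected(self, tiny_phantom):
        with pytest.raises(GeometryError):
            embed_focal_lesion(tiny_phantom, (2.0, 2.0, 2.0), 0.05, -0.2)

    @pytest.mark.parametrize("shrink", [0.05])
    def test_volume_shrink_calibrated(self, tiny_phantom, tiny_spec, tiny_fem,
                                      shrink):
        _, labels = tiny_phantom
        _, out_lab, _ = embed_focal_lesion(
            tiny_phantom, tiny_spec.prostate_center, shrink, 0.0,
            fem=tiny_fem, taper_mm=6.0)
        pre = organ_volume(labels, PROSTATE)
        post = organ_volume(out_lab, PROSTATE)
        assert (post - pre) / pre == pytest.approx(-shrink, abs=0.005)

    def test_deformation_peak_near_site(self, tiny_phantom, tiny_spec,
                                        tiny_fem):
        site = np.asarray(tiny_spec.prostate_center) + np.array([3.0, 0, 0])
        _, _, fld = embed_focal_lesion(tiny_phantom, site, 0.05, 0.0,
                                       fem=tiny_fem, taper_mm=6.0)
        mags = fld.magnitudes()
        peak = np.unravel_index(np.argmax(mags), mags.shape)
        peak_mm = fld.voxel_to_world(np.asarray(peak))
        assert np.linalg.norm(peak_mm - site) < 10.0

    def test_intensity_change_confined_to_ball(self, tiny_phantom, tiny_spec,
                                               tiny_fem):
        img, _ = tiny_phantom
        out_img, _, _ = embed_focal_lesion(
            tiny_phantom, tiny_spec.prostate_center, 0.0, -0.5,
            fem=tiny_fem, intensity_radius_mm=5.0)
        pts = img.grid_points()
        d = np.linalg.norm(pts - np.asarray(tiny_spec.prostate_center),
                           axis=-1)
        outside = d > 6.0
        assert np.array_equal(out_img.data[outside], img.data[outside])
        assert not np.array_equal(out_img.data[~outside], img.data[~outside])
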