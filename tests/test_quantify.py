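"""Resampling, mask operations, relaxation corrections and calibration."""

import logging

import numpy as np
import pytest
from scipy import ndimage

from natsc.core import (
    BLOOD_RELAXATION,
    PROSTATE_RELAXATION,
    RelaxationSet,
    ROIMask,
    SequenceParams,
    SodiumImage,
)
from natsc.quantify import (
    CalibrationModel,
    calibrate_from_fbv,
    derive_tz,
    erode_mask,
    mirror_contralateral,
    quantify_roi,
    reference_stability,
    relaxation_factor,
    resample_to_grid,
)

SEQ = SequenceParams()


def _ball_mask(n, center, radius, spacing=1.0, role="other", name=None):
    x = (np.arange(n) - n // 2) * spacing
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    m = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2
    return ROIMask(mask=m, role=role, spacing=np.full(3, float(spacing)), name=name)


class TestResample:
    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(0)
        img = SodiumImage(rng.random((12, 12, 12)), np.full(3, 2.0))
        out = resample_to_grid(img, (2.0,) * 3, (12, 12, 12))
        assert np.allclose(out.data, img.data, rtol=1e-12)

    def test_anisotropic_target_shape(self):
        img = SodiumImage(np.ones((32, 32, 32)), np.full(3, 2.55))
        out = resample_to_grid(img, (0.7, 0.7, 3.0), (64, 64, 16))
        assert out.shape == (64, 64, 16)
        assert np.allclose(out.spacing, (0.7, 0.7, 3.0))

    def test_shift_moves_point_by_one_target_voxel(self):
        n = 16
        img = SodiumImage(np.zeros((n, n, n)), np.full(3, 2.0))
        img.data[8, 8, 8] = 1.0
        out = resample_to_grid(img, (2.0,) * 3, (n, n, n), shift=(2.0, 0.0, 0.0))
        peak = np.unravel_index(np.argmax(out.data), out.data.shape)
        assert peak == (9, 8, 8)

    def test_disjoint_fov_rejected(self):
        img = SodiumImage(np.ones((8, 8, 8)), np.ones(3))
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid(img, (1.0,) * 3, (8, 8, 8), shift=(500.0, 0.0, 0.0))


class TestDeriveTZ:
    def test_set_arithmetic_on_nested_balls(self):
        wp = _ball_mask(32, (0, 0, 0), 12, role="WP")
        pz = _ball_mask(32, (0, 0, 0), 7, role="PZ")
        tz = derive_tz(wp, pz)
        assert tz.n_voxels == wp.n_voxels - pz.n_voxels
        assert not (tz.mask & pz.mask).any()

    def test_pz_equal_wp_raises(self):
        wp = _ball_mask(16, (0, 0, 0), 5, role="WP")
        pz = wp.with_mask(wp.mask)
        with pytest.raises(ValueError, match="empty"):
            derive_tz(wp, pz)

    def test_pz_outside_wp_clipped_with_warning(self, caplog):
        wp = _ball_mask(32, (0, 0, 0), 8, role="WP")
        pz = _ball_mask(32, (6, 0, 0), 5, role="PZ")  # pokes outside
        with caplog.at_level(logging.WARNING):
            tz = derive_tz(wp, pz)
        assert "clipping" in caplog.text
        assert np.array_equal(tz.mask, wp.mask & ~pz.mask)


class TestMirror:
    def test_midline_lesion_maps_to_itself(self):
        les = _ball_mask(32, (0, 3, -2), 4, role="lesion")
        out = mirror_contralateral(les)
        assert np.array_equal(out.mask, les.mask)

    def test_offset_lesion_reflects(self):
        les = _ball_mask(32, (5, 0, 0), 3, role="lesion")
        out = mirror_contralateral(les)
        expected = _ball_mask(32, (-5, 0, 0), 3, role="lesion")
        assert np.array_equal(out.mask, expected.mask)

    def test_two_disjoint_lesions_stay_disjoint_with_same_counts(self):
        a = _ball_mask(48, (8, 4, 0), 3).mask
        b = _ball_mask(48, (14, -6, 2), 4).mask
        les = ROIMask(mask=a | b, role="lesion", spacing=np.ones(3))
        out = mirror_contralateral(les)
        assert out.n_voxels == les.n_voxels
        ref_a = _ball_mask(48, (-8, 4, 0), 3).mask
        ref_b = _ball_mask(48, (-14, -6, 2), 4).mask
        assert np.array_equal(out.mask, ref_a | ref_b)

    def test_mirror_leaving_grid_rejected(self):
        les = _ball_mask(16, (6, 0, 0), 1, role="lesion")
        with pytest.raises(ValueError, match="outside"):
            mirror_contralateral(les, midline_index=15.0)

    def test_empty_lesion_rejected(self):
        empty = ROIMask(mask=np.zeros((8, 8, 8), bool), role="lesion", spacing=np.ones(3))
        with pytest.raises(ValueError, match="empty"):
            mirror_contralateral(empty)


class TestErode:
    def test_zero_distance_is_identity(self):
        roi = _ball_mask(24, (0, 0, 0), 8)
        assert erode_mask(roi, 0.0) is roi

    def test_ball_erosion_matches_distance_transform_oracle(self):
        roi = _ball_mask(48, (0, 0, 0), 10.0, spacing=1.0)
        out = erode_mask(roi, 5.2)
        edt = ndimage.distance_transform_edt(out.mask)
        # remaining maximal depth ~ 10 - 5.2, within a voxel of discretisation
        assert edt.max() == pytest.approx(4.8, abs=1.0)

    def test_metric_erosion_respects_anisotropic_spacing(self):
        m = np.zeros((20, 20, 20), bool)
        m[5:15, 5:15, 5:15] = True
        roi = ROIMask(mask=m, role="other", spacing=np.array([1.0, 1.0, 4.0]))
        out = erode_mask(roi, 1.5)
        # 1.5 mm removes one voxel layer along the 1 mm axes, none along 4 mm
        assert out.mask[:, :, 5].any() and out.mask[:, :, 14].any()
        assert not out.mask[5, :, :].any() and not out.mask[14, :, :].any()

    def test_monotone_in_distance(self):
        roi = _ball_mask(40, (0, 0, 0), 12)
        counts = [erode_mask(roi, d).n_voxels for d in (0, 2, 4, 6)]
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_emptying_erosion_names_roi_and_distance(self):
        roi = _ball_mask(24, (0, 0, 0), 3, name="PZ-shell")
        with pytest.raises(ValueError, match="PZ-shell.*8.0"):
            erode_mask(roi, 8.0)


class TestRelaxationFactor:
    def test_blood_closed_form(self):
        f = relaxation_factor(BLOOD_RELAXATION, SEQ)
        assert f == pytest.approx(0.9201, abs=5e-5)

    def test_prostate_biexp_closed_form(self):
        f = relaxation_factor(PROSTATE_RELAXATION, SEQ, weights=(0.6, 0.4))
        assert f == pytest.approx(0.8322, abs=5e-5)

    def test_limit_goes_to_one(self):
        relax = RelaxationSet(t1=30.0, mode="mono", t2_star=20.0)
        f = relaxation_factor(relax, SequenceParams(tr=1e9, te=1e-12))
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            relaxation_factor(PROSTATE_RELAXATION, SEQ, weights=(0.7, 0.4))

    def test_nonpositive_times_rejected_at_construction(self):
        with pytest.raises(ValueError):
            RelaxationSet(t1=-1.0, mode="mono", t2_star=10.0)
        with pytest.raises(ValueError):
            RelaxationSet(t1=10.0, mode="biexp", t2_fast=8.0, t2_slow=4.0)


class TestCalibration:
    def _fbv_setup(self, si=1000.0):
        n = 32
        img = SodiumImage(np.full((n, n, n), si), np.full(3, 2.0))
        left = _ball_mask(n, (-10, 0, 0), 4, spacing=2.0, role="FBV_left")
        right = _ball_mask(n, (10, 0, 0), 4, spacing=2.0, role="FBV_right")
        return img, left, right

    def test_slope_arithmetic(self):
        img, left, right = self._fbv_setup()
        factor = relaxation_factor(BLOOD_RELAXATION, SEQ)
        img.data *= factor  # corrected reference SI becomes exactly 1000
        cal = calibrate_from_fbv(img, left, right, BLOOD_RELAXATION, SEQ, 81.0)
        assert cal.corrected_reference_si == pytest.approx(1000.0, rel=1e-12)
        assert cal.slope == pytest.approx(0.081, rel=1e-12)

    def test_default_reference_echoed_in_provenance(self):
        img, left, right = self._fbv_setup()
        cal = calibrate_from_fbv(img, left, right, BLOOD_RELAXATION, SEQ)
        assert cal.provenance["reference_tsc_mM"] == 81.0
        assert cal.reference_tsc == 81.0

    def test_empty_reference_rejected(self):
        img, left, right = self._fbv_setup()
        empty = left.with_mask(np.zeros_like(left.mask))
        with pytest.raises(ValueError, match="non-empty"):
            calibrate_from_fbv(img, empty, right, BLOOD_RELAXATION, SEQ)

    def test_invalid_slope_construction_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel(slope=1.0, reference_tsc=81.0, corrected_reference_si=50.0)

    def test_quantify_uniform_compartment_recovers_exactly(self):
        n = 32
        factor = relaxation_factor(PROSTATE_RELAXATION, SEQ)
        img = SodiumImage(np.full((n, n, n), 40.0 * factor), np.full(3, 2.0))
        blood_f = relaxation_factor(BLOOD_RELAXATION, SEQ)
        left = _ball_mask(n, (-10, 0, 0), 4, spacing=2.0, role="FBV_left")
        right = _ball_mask(n, (10, 0, 0), 4, spacing=2.0, role="FBV_right")
        ref = SodiumImage(np.full((n, n, n), 81.0 * blood_f), np.full(3, 2.0))
        cal = calibrate_from_fbv(ref, left, right, BLOOD_RELAXATION, SEQ)
        roi = _ball_mask(n, (0, 0, 0), 8, spacing=2.0, role="other")
        stats = quantify_roi(img, roi, cal, PROSTATE_RELAXATION, SEQ, erosion=0.0)
        assert stats.mean_tsc == pytest.approx(40.0, abs=1e-9)
        assert stats.sd_tsc == pytest.approx(0.0, abs=1e-9)

    def test_erosion_reduces_voxel_count(self):
        n = 32
        img = SodiumImage(np.ones((n, n, n)), np.full(3, 2.0))
        cal = CalibrationModel(slope=81.0, reference_tsc=81.0, corrected_reference_si=1.0)
        roi = _ball_mask(n, (0, 0, 0), 12, spacing=2.0, role="WP")
        full = quantify_roi(img, roi, cal, PROSTATE_RELAXATION, SEQ, erosion=0.0)
        eroded = quantify_roi(img, roi, cal, PROSTATE_RELAXATION, SEQ, erosion=5.2)
        assert eroded.n_voxels < full.n_voxels

    def test_role_bound_default_erosion_applied(self):
        n = 32
        img = SodiumImage(np.ones((n, n, n)), np.full(3, 2.0))
        cal = CalibrationModel(slope=81.0, reference_tsc=81.0, corrected_reference_si=1.0)
        roi = _ball_mask(n, (0, 0, 0), 12, spacing=2.0, role="WP")
        stats = quantify_roi(img, roi, cal, PROSTATE_RELAXATION, SEQ)
        assert stats.erosion_mm == 5.2
        lesion = _ball_mask(n, (0, 0, 0), 6, spacing=2.0, role="lesion")
        assert quantify_roi(img, lesion, cal, PROSTATE_RELAXATION, SEQ).erosion_mm == 0.0


class TestReferenceStability:
    def _stats(self, image_values, side):
        n = 32
        img = SodiumImage(image_values, np.full(3, 2.0))
        roi = _ball_mask(n, (-10 if side == "left" else 10, 0, 0), 4, spacing=2.0,
                         role=f"FBV_{side}")
        cal = CalibrationModel(slope=1.0, reference_tsc=81.0, corrected_reference_si=81.0)
        blood_f = relaxation_factor(BLOOD_RELAXATION, SEQ)
        return quantify_roi(img, roi, cal, BLOOD_RELAXATION, SEQ, erosion=0.0)

    def test_identical_sides_have_zero_difference(self):
        vals = np.full((32, 32, 32), 50.0)
        left = self._stats(vals, "left")
        right = self._stats(vals, "right")
        out = reference_stability(left, right)
        assert out["abs_difference_mM"] == 0.0

    def test_difference_grows_with_asymmetry(self):
        base = np.full((32, 32, 32), 50.0)
        asym = base.copy()
        asym[16:] *= 1.1  # right side brighter
        l0, r0 = self._stats(base, "left"), self._stats(base, "right")
        l1, r1 = self._stats(asym, "left"), self._stats(asym, "right")
        assert reference_stability(l1, r1)["abs_difference_mM"] > \
            reference_stability(l0, r0)["abs_difference_mM"]
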