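"""Phantom construction, sensitivities, signal model and k-space synthesis."""

import numpy as np
import pytest

from natsc.core import SequenceParams, RelaxationSet
from natsc.gridding import nudft_forward
from natsc.phantom import (
    CompartmentSpec,
    Ellipsoid,
    PhantomGeometry,
    Region,
    build_phantom,
    default_geometry,
    sample_kspace,
    simulate_sensitivities,
    steady_state_signal,
)
from natsc.quantify import relaxation_factor
from natsc.trajectory import make_trajectory
from natsc.core import BLOOD_RELAXATION, PROSTATE_RELAXATION

GRID = (64, 64, 64)
SPACING = (2.5, 2.5, 2.5)


@pytest.fixture(scope="module")
def default_phantom():
    return build_phantom(GRID, SPACING)


class TestBuildPhantom:
    def test_fbv_voxels_carry_blood_tsc(self, default_phantom):
        phantom, rois = default_phantom
        for side in ("FBV_left", "FBV_right"):
            assert np.all(phantom.tsc_map[rois[side].mask] == 81.0)

    def test_zonal_truth_means_are_exact(self, default_phantom):
        phantom, rois = default_phantom
        assert phantom.tsc_map[rois["PZ"].mask].mean() == pytest.approx(40.7)
        assert phantom.tsc_map[rois["TZ"].mask].mean() == pytest.approx(37.5)
        assert phantom.tsc_map[rois["lesion"].mask].mean() == pytest.approx(32.2)

    def test_tsc_map_is_pure_function_of_labels(self, default_phantom):
        phantom, _ = default_phantom
        assert np.array_equal(phantom.tsc_map, phantom.rederive_tsc_map())

    def test_wp_is_union_of_zones_and_lesion(self, default_phantom):
        _, rois = default_phantom
        union = rois["PZ"].mask | rois["TZ"].mask | rois["lesion"].mask
        assert np.array_equal(rois["WP"].mask, union)

    def test_contralateral_mirrors_lesion_voxel_count(self, default_phantom):
        _, rois = default_phantom
        assert rois["contralateral"].n_voxels == rois["lesion"].n_voxels
        assert not (rois["contralateral"].mask & rois["lesion"].mask).any()

    def test_empty_geometry_is_all_background(self):
        geo = PhantomGeometry(compartments=[], background_tsc=17.0)
        phantom, rois = build_phantom((16, 16, 16), (4, 4, 4), geo)
        assert np.all(phantom.labels == 0)
        assert np.all(phantom.tsc_map == 17.0)
        assert rois == {}

    def test_conflicting_overlap_raises_with_pair_names(self):
        e = Ellipsoid((0, 0, 0), (20, 20, 20))
        geo = PhantomGeometry(
            compartments=[
                CompartmentSpec("first", 1, 30.0, PROSTATE_RELAXATION, Region(e)),
                CompartmentSpec("second", 2, 40.0, PROSTATE_RELAXATION, Region(e)),
            ]
        )
        with pytest.raises(ValueError, match="second.*first"):
            build_phantom((24, 24, 24), (4, 4, 4), geo)

    def test_lesion_is_inside_peripheral_zone_bed(self, default_phantom):
        phantom, rois = default_phantom
        # carving removed the lesion voxels from the PZ
        assert not (rois["lesion"].mask & rois["PZ"].mask).any()


class TestSensitivities:
    def test_constant_option_gives_unit_field(self):
        prof = simulate_sensitivities((8, 8, 8), n_channels=1, seed=0, constant=True)
        assert np.all(prof.sensitivities == 1.0)

    def test_same_seed_is_bit_identical(self):
        a = simulate_sensitivities((16, 16, 16), 16, seed=5)
        b = simulate_sensitivities((16, 16, 16), 16, seed=5)
        assert np.array_equal(a.sensitivities, b.sensitivities)

    def test_different_seed_differs(self):
        a = simulate_sensitivities((16, 16, 16), 16, seed=5)
        b = simulate_sensitivities((16, 16, 16), 16, seed=6)
        assert not np.array_equal(a.sensitivities, b.sensitivities)

    def test_rss_positive_everywhere(self):
        prof = simulate_sensitivities((32, 32, 32), 16, seed=0, spacing=SPACING)
        assert prof.rss().min() > 0

    def test_smoothness(self):
        prof = simulate_sensitivities((32, 32, 32), 4, seed=1, spacing=(5, 5, 5))
        mag = np.abs(prof.sensitivities[0])
        grad = np.abs(np.diff(mag, axis=0)).max()
        assert grad < 0.1 * mag.max()


class TestSteadyStateSignal:
    def test_limits_reduce_to_tsc_map(self, default_phantom):
        phantom, _ = default_phantom
        seq = SequenceParams(tr=1e9, te=1e-9)
        sig = steady_state_signal(phantom, seq)
        assert np.allclose(sig, phantom.tsc_map, rtol=1e-6)

    def test_blood_closed_form(self, default_phantom):
        phantom, rois = default_phantom
        seq = SequenceParams()
        sig = steady_state_signal(phantom, seq)
        expected = 81.0 * (1 - np.exp(-120 / 31.9)) * np.exp(-1.2 / 20.1)
        assert sig[rois["FBV_left"].mask].mean() == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(74.5, abs=0.05)

    def test_prostate_biexponential_closed_form(self, default_phantom):
        phantom, rois = default_phantom
        sig = steady_state_signal(phantom, SequenceParams())
        factor = (1 - np.exp(-120 / 38.8)) * (
            0.6 * np.exp(-1.2 / 6.8) + 0.4 * np.exp(-1.2 / 14.8)
        )
        assert factor == pytest.approx(0.832, abs=5e-4)
        assert sig[rois["PZ"].mask].mean() == pytest.approx(40.7 * factor, rel=1e-12)

    def test_relaxation_correction_inverts_signal_model(self, default_phantom):
        """Dividing by quantify.relaxation_factor must recover the truth map
        to double precision, compartment by compartment."""
        phantom, _ = default_phantom
        seq = SequenceParams()
        sig = steady_state_signal(phantom, seq)
        for comp in phantom.compartments:
            m = phantom.labels == comp.label
            rec = sig[m] / relaxation_factor(comp.relaxation, seq)
            assert np.allclose(rec, comp.tsc_true, rtol=1e-10)


@pytest.fixture(scope="module")
def tiny():
    seq = SequenceParams(n_spokes=120, n_samples=24)
    traj = make_trajectory(seq)
    sens = simulate_sensitivities((16, 16, 16), 2, seed=0, spacing=(5, 5, 5))
    return seq, traj, sens


class TestSampleKspace:

    def test_delta_image_gives_flat_dc_per_channel(self, tiny):
        _, traj, sens = tiny
        sig = np.zeros((16, 16, 16))
        sig[8, 8, 8] = 2.0
        ksp = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), method="exact")
        for c in range(2):
            expected = 2.0 * 125.0 * sens.sensitivities[c, 8, 8, 8]
            assert np.allclose(ksp.data[c], expected, rtol=1e-12)

    def test_noiseless_calls_are_bit_identical(self, tiny):
        _, traj, sens = tiny
        rng = np.random.default_rng(0)
        sig = rng.random((16, 16, 16))
        a = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), method="exact")
        b = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), method="exact")
        assert np.array_equal(a.data, b.data)

    def test_noise_is_seed_deterministic_and_seed_sensitive(self, tiny):
        _, traj, sens = tiny
        sig = np.ones((16, 16, 16))
        a = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), noise_sigma=1.0, seed=3)
        b = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), noise_sigma=1.0, seed=3)
        c = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), noise_sigma=1.0, seed=4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_ball_matches_independent_direct_sum(self, tiny):
        """Exact NUDFT versus an independent brute-force voxel sum."""
        _, traj, sens = tiny
        x = np.arange(16) - 8
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        ball = ((X**2 + Y**2 + Z**2) <= 9).astype(float)
        ksp = sample_kspace(ball, sens, traj, spacing=(5, 5, 5), method="exact")
        k = traj.coords[::40].reshape(-1, 3)  # subset for speed
        vox = np.argwhere(ball > 0)
        phases = np.exp(-2j * np.pi * (k @ ((vox - 8) * 5.0).T))
        brute = 125.0 * phases @ (ball[ball > 0] * sens.sensitivities[0][ball > 0])
        assert np.allclose(ksp.data[0, ::40].reshape(-1), brute, rtol=1e-10)

    def test_ball_approximates_continuous_sphere_transform(self, tiny):
        """The sampled values should follow the analytic jinc-like profile of
        a uniform sphere at low |k| (discretisation limits the agreement)."""
        _, traj, sens0 = tiny
        sens = simulate_sensitivities((16, 16, 16), 1, seed=0, constant=True)
        x = (np.arange(16) - 8) * 5.0
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        R = 21.0
        ball = ((X**2 + Y**2 + Z**2) <= R**2).astype(float)
        ksp = sample_kspace(ball, sens, traj, spacing=(5, 5, 5), method="exact")
        r = np.linalg.norm(traj.coords[0], axis=-1)
        lo = r < 0.35 * r.max()
        kr = 2 * np.pi * r[lo] * R
        analytic = 4 * np.pi * R**3 * (np.sin(kr) - kr * np.cos(kr)) / kr**3
        measured = ksp.data[0, 0, lo].real
        assert np.allclose(measured, analytic, rtol=0.12, atol=0.02 * analytic.max())

    def test_gridded_matches_exact(self, tiny):
        _, traj, sens = tiny
        rng = np.random.default_rng(1)
        sig = np.zeros((16, 16, 16))
        sig[4:12, 4:12, 4:12] = rng.random((8, 8, 8))
        a = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), method="exact")
        b = sample_kspace(sig, sens, traj, spacing=(5, 5, 5), method="gridded")
        scale = np.abs(a.data).max()
        assert np.abs(a.data - b.data).max() / scale < 5e-3

    def test_trajectory_beyond_nyquist_rejected(self, tiny):
        seq, traj, sens = tiny
        sig = np.ones((16, 16, 16))
        with pytest.raises(ValueError, match="Nyquist"):
            sample_kspace(sig, sens, traj, spacing=(20, 20, 20))

    def test_missing_relaxation_named_in_error(self):
        from natsc.phantom import PhantomVolume, TissueCompartment

        comp = TissueCompartment(0, "background", 10.0, BLOOD_RELAXATION)
        vol = PhantomVolume(
            labels=np.zeros((4, 4, 4), dtype=int),
            tsc_map=np.full((4, 4, 4), 10.0),
            spacing=np.array([1.0, 1.0, 1.0]),
            compartments=[comp],
        )
        object.__setattr__(comp, "relaxation", None)
        with pytest.raises(ValueError, match="background"):
            steady_state_signal(vol, SequenceParams())
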