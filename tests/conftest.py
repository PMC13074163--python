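"""Shared fixtures.

The expensive end-to-end objects (full-size noiseless pipeline run, the
noise-matched noisy replicates) are session-scoped and shared across the
whole suite; small-scale synthetic objects are rebuilt per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from natsc.config import default_config
from natsc.core import SequenceParams, child_rng
from natsc.phantom import KSpaceData
from natsc.pipeline import (
    combine_and_correct,
    noise_sigma_for_snr,
    quantify_stage,
    reconstruct_stage,
    run_pipeline,
)
from natsc.quantify import erode_mask
from natsc.trajectory import make_trajectory

# eroded-mask truth means of the default phantom compartments (mM)
TRUTH = {
    "PZ": 40.7,
    "TZ": 37.5,
    "lesion": 32.2,
    "contralateral": 40.7,
    "FBV_left": 81.0,
    "FBV_right": 81.0,
}


@pytest.fixture(scope="session")
def small_seq() -> SequenceParams:
    return SequenceParams(n_spokes=1500, n_samples=64)


@pytest.fixture(scope="session")
def small_traj(small_seq):
    return make_trajectory(small_seq)


@pytest.fixture(scope="session")
def full_run():
    """Noiseless default pipeline at the study's acquisition size."""
    return run_pipeline(default_config(), seed=1, save=False)


@pytest.fixture(scope="session")
def wp_truth(full_run):
    mask = erode_mask(full_run.rois["WP"], 5.2).mask
    return float(full_run.phantom.tsc_map[mask].mean())


def _rerun_with_kspace(cfg, ksp, seq, rois, phantom):
    """Post-simulation stages (recon x2, combine, B1, quantify) on given data."""
    plain = reconstruct_stage(cfg, ksp, seq, hanning=False)
    ref = reconstruct_stage(cfg, ksp, seq, hanning=True)
    tissue_img, ref_img, _, _ = combine_and_correct(cfg, plain, ref)
    return quantify_stage(
        cfg, tissue_img, ref_img, rois, seq,
        target_spacing=phantom.spacing, target_shape=phantom.labels.shape,
    )


@pytest.fixture(scope="session")
def noisy_reports(full_run):
    """Five noise realisations at interior SNR ~ 20, reusing the noiseless
    k-space of the session run."""
    cfg = default_config()
    tz = erode_mask(full_run.rois["TZ"], 5.2).mask
    sigma = noise_sigma_for_snr(
        20.0, full_run.tissue_image, tz, full_run.kspace, full_run.sequence,
        cfg, seed=1,
    )
    reports = []
    for seed in range(5):
        rng = child_rng(seed, "test-noise")
        noise = rng.standard_normal(full_run.kspace.data.shape) + 1j * rng.standard_normal(
            full_run.kspace.data.shape
        )
        noisy = KSpaceData(
            data=full_run.kspace.data + sigma * noise,
            trajectory=full_run.kspace.trajectory,
            noise_sigma=sigma,
            seed=seed,
        )
        reports.append(
            _rerun_with_kspace(cfg, noisy, full_run.sequence, full_run.rois, full_run.phantom)
        )
    return reports
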