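"""File formats: NIfTI volumes/masks, k-space containers, report tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ROIMask, SodiumImage
from .phantom import KSpaceData, PhantomVolume
from .trajectory import Trajectory

__all__ = [
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_phantom",
    "save_kspace",
    "load_kspace",
    "save_report",
]


def _affine(spacing, origin):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_image(image: SodiumImage, path) -> None:
    data = image.data
    if np.iscomplexobj(data):
        data = np.abs(data)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(image.spacing, image.origin)), str(path))


def load_image(path) -> SodiumImage:
    img = nib.load(str(path))
    aff = img.affine
    return SodiumImage(
        np.asarray(img.get_fdata(), dtype=float),
        spacing=np.abs(np.diag(aff)[:3]),
        origin=aff[:3, 3],
    )


def save_mask(mask: ROIMask, path) -> None:
    nib.save(
        nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.spacing, mask.origin)),
        str(path),
    )


def load_mask(path, role: str = "other", name: str | None = None) -> ROIMask:
    img = nib.load(str(path))
    aff = img.affine
    return ROIMask(
        mask=np.asarray(img.get_fdata()) > 0.5,
        role=role,
        spacing=np.abs(np.diag(aff)[:3]),
        origin=aff[:3, 3],
        name=name,
    )


def save_phantom(phantom: PhantomVolume, rois: dict, outdir) -> None:
    """Write label map, truth map, per-ROI masks and the compartment table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(phantom.spacing, phantom.origin)
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), aff), str(outdir / "labels.nii.gz"))
    nib.save(nib.Nifti1Image(phantom.tsc_map.astype(np.float32), aff), str(outdir / "tsc_truth.nii.gz"))
    rows = []
    for c in phantom.compartments:
        r = c.relaxation
        rows.append(
            {
                "label": c.label,
                "name": c.name,
                "tsc_mM": c.tsc_true,
                "t1_ms": r.t1,
                "mode": r.mode,
                "t2_star_ms": r.t2_star,
                "t2_fast_ms": r.t2_fast,
                "t2_slow_ms": r.t2_slow,
                "fast_fraction": r.fast_fraction if r.mode == "biexp" else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "compartments.csv", index=False)
    for key, roi in rois.items():
        save_mask(roi, outdir / f"mask_{key}.nii.gz")


def save_kspace(ksp: KSpaceData, path) -> None:
    """Shape- and dtype-tagged NumPy container with trajectory coordinates."""
    meta = {
        "noise_sigma": ksp.noise_sigma,
        "seed": ksp.seed,
        "ramp_fraction": ksp.trajectory.ramp_fraction,
        "k_max": ksp.trajectory.k_max,
    }
    np.savez_compressed(
        str(path),
        data=ksp.data.astype(np.complex64),
        coords=ksp.trajectory.coords.astype(np.float32),
        dcf=ksp.trajectory.dcf.astype(np.float64),
        meta=json.dumps(meta),
    )


def load_kspace(path) -> KSpaceData:
    with np.load(str(path), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        traj = Trajectory(
            coords=f["coords"].astype(np.float64),
            dcf=f["dcf"],
            ramp_fraction=meta["ramp_fraction"],
            k_max=meta["k_max"],
        )
        return KSpaceData(
            data=f["data"].astype(np.complex128),
            trajectory=traj,
            noise_sigma=meta["noise_sigma"],
            seed=meta["seed"],
        )


def save_report(report, outdir, stem: str = "tsc_report") -> None:
    """TSCReport as CSV (table) and JSON (table + reference metrics)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    frame.to_csv(outdir / f"{stem}.csv", index=False, float_format="%.6f")
    payload = {
        "rois": frame.to_dict(orient="records"),
        "reference_stability": report.reference,
    }
    if report.calibration is not None:
        payload["calibration"] = {
            "slope_mM_per_unit": report.calibration.slope,
            "reference_tsc_mM": report.calibration.reference_tsc,
            "corrected_reference_si": report.calibration.corrected_reference_si,
            "provenance": report.calibration.provenance,
        }
    (outdir / f"{stem}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
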