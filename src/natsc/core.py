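"""Shared value types for the sodium-MRI quantification pipeline.

Axis convention: axis 0 = left-right (x), axis 1 = anterior-posterior (y),
axis 2 = superior-inferior (z).  World coordinates are in millimetres; the
``origin`` of a volume is the world position of the centre of voxel
``(0, 0, 0)``.  By default volumes are centred on the world origin.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SequenceParams",
    "RelaxationSet",
    "SodiumImage",
    "ROIMask",
    "centered_origin",
    "voxel_centers",
    "child_rng",
    "child_seed",
]

ROI_ROLES = (
    "WP",
    "PZ",
    "TZ",
    "lesion",
    "contralateral",
    "FBV_left",
    "FBV_right",
    "other",
)


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of the 3D radial sodium sequence.

    Defaults follow the clinical protocol: TR/TE = 120/1.2 ms, 90 degree
    excitation, 8000 spokes of 384 samples, 5.1 mm nominal isotropic
    resolution.  Gradient amplitude, slew rate and bandwidth are carried as
    metadata only.
    """

    tr: float = 120.0  # ms
    te: float = 1.2  # ms
    flip_angle: float = 90.0  # degrees
    n_spokes: int = 8000
    n_samples: int = 384
    nominal_resolution: float = 5.1  # mm, isotropic
    gradient_amplitude: float = 3.6  # mT/m, metadata
    slew_rate: float = 170.0  # T/m/s, metadata
    bandwidth: float = 50.0  # Hz/pixel, metadata

    def __post_init__(self) -> None:
        if not (self.tr > self.te > 0):
            raise ValueError(f"require tr > te > 0, got tr={self.tr}, te={self.te}")
        if self.n_spokes < 1 or self.n_samples < 1:
            raise ValueError("n_spokes and n_samples must be >= 1")
        if self.nominal_resolution <= 0:
            raise ValueError("nominal_resolution must be positive")

    @property
    def k_max(self) -> float:
        """Maximum sampled spatial frequency in cycles/mm."""
        return 1.0 / (2.0 * self.nominal_resolution)

    @property
    def acquisition_time_s(self) -> float:
        """Total acquisition time (one excitation per spoke)."""
        return self.tr * 1e-3 * self.n_spokes


@dataclass(frozen=True)
class RelaxationSet:
    """Longitudinal and transverse relaxation parameters of one tissue.

    ``mono`` mode carries a single T2*, ``biexp`` mode a fast and a slow
    T2* component with the fast signal fraction ``fast_fraction``.
    All times in milliseconds.
    """

    t1: float
    mode: Literal["mono", "biexp"] = "mono"
    t2_star: float | None = None
    t2_fast: float | None = None
    t2_slow: float | None = None
    fast_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.mode == "mono":
            if self.t2_star is None or self.t2_star <= 0:
                raise ValueError("mono mode requires t2_star > 0")
        elif self.mode == "biexp":
            if self.t2_fast is None or self.t2_slow is None:
                raise ValueError("biexp mode requires t2_fast and t2_slow")
            if not (0 < self.t2_fast <= self.t2_slow):
                raise ValueError("require 0 < t2_fast <= t2_slow")
            if not (0.0 <= self.fast_fraction <= 1.0):
                raise ValueError("fast_fraction must lie in [0, 1]")
        else:
            raise ValueError(f"unknown relaxation mode {self.mode!r}")


# Literature relaxation values used throughout: blood from in-vivo sodium
# measurements at 3 T, prostate with biexponential transverse decay.
BLOOD_RELAXATION = RelaxationSet(t1=31.9, mode="mono", t2_star=20.1)
PROSTATE_RELAXATION = RelaxationSet(
    t1=38.8, mode="biexp", t2_fast=6.8, t2_slow=14.8, fast_fraction=0.6
)
MUSCLE_RELAXATION = RelaxationSet(t1=29.0, mode="mono", t2_star=13.0)


def centered_origin(shape, spacing) -> np.ndarray:
    """World position of voxel (0,0,0) for a volume centred on the origin.

    Follows the FFT convention: voxel ``N//2`` sits exactly at world zero,
    which keeps image grids and k-space grids aligned across modules.
    """
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    return -(shape // 2).astype(float) * spacing


@dataclass
class SodiumImage:
    """A reconstructed 3D volume with voxel spacing and origin metadata."""

    data: np.ndarray
    spacing: np.ndarray  # mm per axis, length 3
    origin: np.ndarray | None = None  # mm, world position of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("SodiumImage data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.origin is None:
            self.origin = centered_origin(self.data.shape, self.spacing)
        else:
            self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def magnitude(self) -> "SodiumImage":
        return SodiumImage(np.abs(self.data), self.spacing.copy(), self.origin.copy())

    def with_data(self, data: np.ndarray) -> "SodiumImage":
        return SodiumImage(np.asarray(data), self.spacing.copy(), self.origin.copy())


@dataclass
class ROIMask:
    """Binary region-of-interest mask on a stated grid."""

    mask: np.ndarray
    role: str = "other"
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3D")
        if self.role not in ROI_ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}; valid: {ROI_ROLES}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.origin is None:
            self.origin = centered_origin(self.mask.shape, self.spacing)
        else:
            self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.name is None:
            self.name = self.role

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def with_mask(self, mask: np.ndarray) -> "ROIMask":
        return replace(self, mask=np.asarray(mask).astype(bool))


def voxel_centers(shape, spacing, origin=None):
    """World coordinates of all voxel centres, as three broadcastable axes."""
    spacing = np.asarray(spacing, dtype=float)
    if origin is None:
        origin = centered_origin(shape, spacing)
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage child seed from one global seed.

    Uses a CRC of the stage name as a spawn key so each stage sees an
    independent stream while remaining reproducible when run standalone.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))
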