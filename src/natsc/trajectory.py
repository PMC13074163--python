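"""Density-adapted 3D radial k-space trajectory.

Each spoke starts at the k-space centre and reads outward.  The radial
position grows linearly with sample index over the initial gradient ramp
(a fraction ``ramp_fraction`` of the readout) and as ``t**(1/3)`` beyond
it, which keeps the sampling density per unit k-space volume constant on
the outer part of the spoke — the defining property of the
density-adapted readout.  Spoke directions follow a deterministic
generalized (golden-angle) spiral on the sphere, so no random state is
involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SequenceParams

__all__ = ["Trajectory", "make_trajectory", "sphere_spiral_directions"]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class Trajectory:
    """Radial k-space coordinates (cycles/mm) and density-compensation weights.

    ``coords`` has shape (n_spokes, n_samples, 3); ``dcf`` holds the
    k-space volume element of each sample, so that ``sum(dcf)`` equals the
    volume of the sampled k-ball.
    """

    coords: np.ndarray
    dcf: np.ndarray
    ramp_fraction: float
    k_max: float

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_spokes, n_samples, 3)")
        if self.dcf.shape != self.coords.shape[:2]:
            raise ValueError("dcf shape must match coords[:, :, 0]")
        if not np.all(np.isfinite(self.dcf)) or np.any(self.dcf < 0):
            raise ValueError("dcf must be finite and non-negative")

    @property
    def n_spokes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]

    @property
    def radii(self) -> np.ndarray:
        """Radial position of each sample of one spoke (all spokes share it)."""
        return np.linalg.norm(self.coords[0], axis=-1)


def sphere_spiral_directions(n: int) -> np.ndarray:
    """``n`` unit vectors approximately uniform on the sphere (deterministic)."""
    i = np.arange(n)
    z = (2.0 * i + 1.0) / n - 1.0
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * GOLDEN_ANGLE
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def radial_law(t: np.ndarray, ramp_fraction: float, k_max: float):
    """Radius and its derivative dr/dt for normalised readout time t in (0,1].

    Linear on the ramp, cube-root beyond it, with radius *and* slope
    matched at the junction (so the k-space volume element r^2 dr/dt is
    continuous) and r(1) = k_max.
    """
    t = np.asarray(t, dtype=float)
    t0 = ramp_fraction
    c = k_max / np.cbrt(3.0 * t0**2 - 2.0 * t0**3)
    outer = np.maximum(3.0 * t0**2 * t - 2.0 * t0**3, 0.0)
    r = np.where(t <= t0, c * t, c * np.cbrt(outer))
    drdt = np.where(t <= t0, c, c * t0**2 / np.maximum(np.cbrt(outer) ** 2, 1e-300))
    return r, drdt


def make_trajectory(seq: SequenceParams, ramp_fraction: float = 0.25) -> Trajectory:
    """Build the density-adapted radial trajectory for a sequence.

    Parameters
    ----------
    seq:
        Acquisition parameters; ``n_spokes``, ``n_samples`` and
        ``nominal_resolution`` (which fixes ``k_max``) are used.
    ramp_fraction:
        Fraction of the readout spent on the linear gradient ramp, in
        (0, 1].  ``ramp_fraction = 1`` degenerates to a plain radial
        readout with dcf proportional to r**2 everywhere.
    """
    if not (0.0 < ramp_fraction <= 1.0):
        raise ValueError("ramp_fraction must lie in (0, 1]")
    k_max = seq.k_max
    # midpoint sampling avoids a duplicated r=0 sample on every spoke
    t = (np.arange(seq.n_samples) + 0.5) / seq.n_samples
    r, drdt = radial_law(t, ramp_fraction, k_max)

    dirs = sphere_spiral_directions(seq.n_spokes)
    coords = dirs[:, None, :] * r[None, :, None]

    # analytic volume element: (4 pi / n_spokes) * r^2 dr, normalised so the
    # weights sum exactly to the volume of the k-ball
    w = r * r * drdt / seq.n_samples
    w *= (k_max**3 / 3.0) / w.sum()
    dcf_spoke = 4.0 * np.pi / seq.n_spokes * w
    dcf = np.broadcast_to(dcf_spoke, (seq.n_spokes, seq.n_samples)).copy()

    return Trajectory(coords=coords, dcf=dcf, ramp_fraction=ramp_fraction, k_max=k_max)
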