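"""Per-channel gridding reconstruction of radial sodium k-space data.

Each channel is reconstructed independently: density compensation, an
optional radial Hanning taper in k-space, Kaiser-Bessel convolution onto
an oversampled Cartesian grid, symmetric zero-padding by the zero-filling
factor, inverse FFT, deapodization by the analytic kernel transform, and
a crop to the field of view.  With the default zero-filling factor of 2
a 5.1 mm nominal acquisition yields 2.55 mm output voxels.

The optional Hanning taper trades resolution for noise and ringing
suppression: it removes Gibbs oscillation at high-contrast edges (which
stabilises signal averages inside bright blood vessels) at the cost of
roughly doubling the point-spread-function width.  It is therefore off by
default and enabled explicitly where robustness matters more than
resolution (see the pipeline's two-pass quantification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SodiumImage
from .gridding import deapodization_1d, kaiser_bessel_beta, spread
from .phantom import KSpaceData
from .trajectory import Trajectory

__all__ = ["ReconSettings", "grid_reconstruct", "hanning_taper"]


@dataclass(frozen=True)
class ReconSettings:
    """Gridding reconstruction parameters.

    ``kernel_width`` is in oversampled-grid units (the protocol value is
    4); ``kaiser_beta`` defaults to the Beatty formula for the chosen
    width and oversampling; ``zero_fill`` symmetrically zero-pads k-space
    before the inverse FFT, halving the output voxel size at the default
    factor 2.
    """

    kernel_width: float = 4.0
    kaiser_beta: float | None = None
    oversampling: float = 2.0
    zero_fill: int = 2
    hanning: bool = False

    def __post_init__(self) -> None:
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.zero_fill < 1:
            raise ValueError("zero_fill must be >= 1")

    @property
    def beta(self) -> float:
        if self.kaiser_beta is not None:
            return self.kaiser_beta
        return kaiser_bessel_beta(self.kernel_width, self.oversampling)


def hanning_taper(radii: np.ndarray, k_max: float) -> np.ndarray:
    """Radial Hanning window 0.5*(1 + cos(pi r / k_max)) on [0, k_max]."""
    r = np.minimum(np.asarray(radii, dtype=float) / k_max, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * r))


def _recon_matrix(fov_mm: float, nominal_resolution: float) -> int:
    """Even reconstruction matrix size covering the requested field of view."""
    n = int(np.ceil(fov_mm / nominal_resolution))
    return n + (n % 2)


def grid_reconstruct(
    ksp: KSpaceData,
    traj: Trajectory | None = None,
    settings: ReconSettings | None = None,
    fov_mm: float = 160.0,
    nominal_resolution: float | None = None,
) -> list:
    """Reconstruct every channel of radial k-space data.

    Returns a list of complex :class:`SodiumImage`, one per channel, with
    output voxel size ``nominal_resolution / zero_fill`` on a grid
    covering at least ``fov_mm``.  The amplitude convention matches the
    forward model: a noiseless uniform compartment reconstructs to
    approximately its simulated signal amplitude.
    """
    if traj is None:
        traj = ksp.trajectory
    if settings is None:
        settings = ReconSettings()
    if traj.coords.shape[:2] != ksp.data.shape[1:]:
        raise ValueError("trajectory does not match the k-space data")
    if not np.any(traj.dcf > 0):
        raise ValueError("density compensation weights are all zero")

    if nominal_resolution is None:
        nominal_resolution = 1.0 / (2.0 * traj.k_max)
    n = _recon_matrix(fov_mm, nominal_resolution)
    os_ = settings.oversampling
    m0 = int(round(n * os_ / 2)) * 2  # oversampled gridding matrix
    m = m0 * settings.zero_fill  # zero-filled FFT matrix
    if settings.kernel_width > m0:
        raise ValueError("gridding kernel is wider than the k-space grid")
    beta = settings.beta
    # k-grid spacing such that the oversampled image FOV is m0 * resolution
    delta_k = 1.0 / (m0 * nominal_resolution)

    weights = traj.dcf.astype(np.complex128)
    if settings.hanning:
        weights = weights * hanning_taper(traj.radii, traj.k_max)[None, :]

    # separable deapodization on the zero-filled grid, floored to avoid
    # edge blow-up
    dea = deapodization_1d(m, beta, settings.kernel_width)
    dea = np.maximum(dea, 1e-6 * dea.max())

    n_out = n * settings.zero_fill
    lo = m // 2 - n_out // 2
    sl = slice(lo, lo + n_out)
    spacing = nominal_resolution / settings.zero_fill

    images = []
    for c in range(ksp.n_channels):
        vals = ksp.data[c].astype(np.complex128) * weights
        grid = spread(traj.coords, vals, (m0, m0, m0), delta_k, beta, settings.kernel_width)
        if settings.zero_fill > 1:
            padded = np.zeros((m, m, m), dtype=np.complex128)
            off = m // 2 - m0 // 2
            padded[off:off + m0, off:off + m0, off:off + m0] = grid
            grid = padded
        img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * m**3
        img /= dea[:, None, None] * dea[None, :, None] * dea[None, None, :]
        img = img[sl, sl, sl]
        images.append(SodiumImage(np.ascontiguousarray(img), np.full(3, spacing)))
    return images
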