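"""Adaptive coil combination (ACC) of multichannel complex images.

Per local block the channel sample-covariance matrix is formed and its
principal eigenvector taken as the channel weight vector — each channel
is weighted in proportion to its local signal, which maximises the local
signal-to-noise ratio under spatially white noise.  Block weights are
phase-anchored to a single volume-wide reference channel, unit-normalised,
interpolated trilinearly to voxels, and applied as a weighted conjugate
sum whose magnitude is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SodiumImage

__all__ = ["CombineSettings", "adaptive_weights", "apply_weights", "adaptive_combine"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombineSettings:
    """``block_size``: cubic block edge (voxels) for the local covariance;
    ``smoothing``: optional Gaussian sigma (voxels) applied to the
    interpolated weight fields."""

    block_size: int = 8
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.smoothing < 0:
            raise ValueError("smoothing must be non-negative")


def _as_stack(channels) -> tuple:
    """Accepts a complex array (n_ch, x, y, z) or a list of SodiumImage."""
    if isinstance(channels, np.ndarray):
        return channels, None
    imgs = list(channels)
    stack = np.stack([im.data for im in imgs], axis=0)
    return stack, imgs[0]


def adaptive_weights(channels, settings: CombineSettings | None = None) -> np.ndarray:
    """Voxelwise unit-norm channel weights (n_ch, x, y, z), complex."""
    settings = settings or CombineSettings()
    stack, _ = _as_stack(channels)
    if stack.ndim != 4:
        raise ValueError("expected a (n_channels, x, y, z) stack")
    n_ch = stack.shape[0]
    shape = stack.shape[1:]
    b = settings.block_size
    nblocks = [max(1, int(np.ceil(s / b))) for s in shape]

    wb = np.zeros((n_ch, *nblocks), dtype=np.complex128)
    fallback = 0
    for ix in range(nblocks[0]):
        for iy in range(nblocks[1]):
            for iz in range(nblocks[2]):
                sl = (
                    slice(None),
                    slice(ix * b, min((ix + 1) * b, shape[0])),
                    slice(iy * b, min((iy + 1) * b, shape[1])),
                    slice(iz * b, min((iz + 1) * b, shape[2])),
                )
                x = stack[sl].reshape(n_ch, -1)
                cov = x @ x.conj().T
                tr = np.trace(cov).real
                if tr <= 0 or not np.isfinite(tr):
                    w = np.ones(n_ch, dtype=np.complex128) / np.sqrt(n_ch)
                    fallback += 1
                else:
                    vals, vecs = np.linalg.eigh(cov)
                    w = vecs[:, -1]
                wb[:, ix, iy, iz] = w
    if fallback:
        log.warning("adaptive combination: %d zero-variance blocks fell back to uniform weights", fallback)

    # phase anchor: rotate every block so one volume-wide reference channel
    # (the one carrying the most weight overall) is real-positive.  A single
    # global anchor keeps neighbouring blocks phase-consistent, which a
    # per-block anchor does not guarantee, so the trilinear interpolation
    # below stays meaningful.
    ref = int(np.argmax(np.abs(wb).reshape(n_ch, -1).sum(axis=1)))
    ref_component = wb[ref].copy()
    weak = np.abs(ref_component) < 1e-12
    ref_component[weak] = 1.0  # leave degenerate blocks unrotated
    wb = wb * np.exp(-1j * np.angle(ref_component))[None]

    # interpolate block-centre weights to voxel positions
    coords = [
        np.clip((np.arange(shape[i]) + 0.5) / b - 0.5, 0, nblocks[i] - 1) for i in range(3)
    ]
    cgrid = np.meshgrid(*coords, indexing="ij")
    weights = np.empty((n_ch, *shape), dtype=np.complex128)
    for c in range(n_ch):
        re = ndimage.map_coordinates(wb[c].real, cgrid, order=1, mode="nearest")
        im = ndimage.map_coordinates(wb[c].imag, cgrid, order=1, mode="nearest")
        weights[c] = re + 1j * im
    if settings.smoothing > 0:
        for c in range(n_ch):
            weights[c] = (
                ndimage.gaussian_filter(weights[c].real, settings.smoothing, mode="nearest")
                + 1j * ndimage.gaussian_filter(weights[c].imag, settings.smoothing, mode="nearest")
            )
    norm = np.sqrt((np.abs(weights) ** 2).sum(axis=0))
    norm = np.maximum(norm, np.finfo(float).tiny)
    return weights / norm


def apply_weights(channels, weights: np.ndarray) -> SodiumImage:
    """Magnitude of the weighted conjugate channel sum."""
    stack, ref = _as_stack(channels)
    combined = np.abs((weights.conj() * stack).sum(axis=0))
    if ref is not None:
        return SodiumImage(combined, ref.spacing.copy(), ref.origin.copy())
    return SodiumImage(combined, np.ones(3))


def adaptive_combine(channels, settings: CombineSettings | None = None,
                     return_weights: bool = False):
    """Adaptively combine a multichannel stack into one magnitude image."""
    weights = adaptive_weights(channels, settings)
    out = apply_weights(channels, weights)
    if return_weights:
        return out, weights
    return out
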