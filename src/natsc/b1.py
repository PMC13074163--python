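"""Receive-field (B1-) inhomogeneity correction by low-pass filtering.

The combined sodium image is smoothed with a cubic 3D Gaussian filter
(sigma1, odd filter size), thresholded into a support mask M, and M is
smoothed with a second, wider Gaussian (sigma2).  The correction map is
the ratio of the smoothed image to the smoothed mask; dividing the image
by this map removes the slowly varying receive-sensitivity bias while
leaving anatomical detail untouched.  With ``normalize_map`` the map is
rescaled so the mean intensity inside the thresholded mask is preserved
(the absolute scale is irrelevant after internal-reference calibration,
but scale-preserving maps keep diagnostics comparable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import SodiumImage

__all__ = ["B1Settings", "lowpass_b1_correct"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class B1Settings:
    """Filter parameters in voxels; protocol defaults are sigma 10 with a
    41-voxel kernel and sigma 20 with an 81-voxel kernel."""

    sigma1: float = 10.0
    size1: int = 41
    sigma2: float = 20.0
    size2: int = 81
    threshold_method: str = "otsu"  # or "fraction_of_max"
    threshold_value: float = 0.1
    normalize_map: bool = True

    def __post_init__(self) -> None:
        for sigma, size, name in ((self.sigma1, self.size1, "1"), (self.sigma2, self.size2, "2")):
            if sigma <= 0:
                raise ValueError(f"sigma{name} must be positive")
            if size % 2 == 0 or size < 2 * int(np.ceil(2 * sigma)) + 1:
                raise ValueError(
                    f"size{name} must be odd and at least 2*ceil(2*sigma{name})+1"
                )
        if self.threshold_method not in ("otsu", "fraction_of_max"):
            raise ValueError("threshold_method must be 'otsu' or 'fraction_of_max'")
        if self.threshold_method == "fraction_of_max" and not (0 < self.threshold_value < 1):
            raise ValueError("threshold_value must lie in (0, 1)")


def _cubic_gaussian(data: np.ndarray, sigma: float, size: int) -> np.ndarray:
    # truncate such that the kernel half-width is (size-1)/2 voxels
    truncate = ((size - 1) / 2) / sigma
    return ndimage.gaussian_filter(data, sigma=sigma, truncate=truncate, mode="reflect")


def lowpass_b1_correct(
    image: SodiumImage, settings: B1Settings | None = None
) -> tuple:
    """Correct a magnitude image for receive-field bias.

    Returns ``(corrected, correction_map, support_mask)``.  The corrected
    image equals the input divided by the map inside the support and is
    left untouched outside (the support mask flags where the correction is
    defined).  Raises if thresholding produces an empty mask.
    """
    settings = settings or B1Settings()
    data = image.data
    if np.iscomplexobj(data):
        data = np.abs(data)
    if np.any(data < 0):
        raise ValueError("B1 correction expects a non-negative magnitude image")

    na_lp = _cubic_gaussian(data, settings.sigma1, settings.size1)
    if settings.threshold_method == "otsu":
        thr = threshold_otsu(na_lp)
    else:
        thr = settings.threshold_value * na_lp.max()
    mask = na_lp > thr
    if not mask.any():
        raise ValueError(
            "B1 support mask is empty; lower the threshold (threshold_method/"
            "threshold_value)"
        )
    m_lp = _cubic_gaussian(mask.astype(float), settings.sigma2, settings.size2)

    eps = 1e-6 * m_lp.max()
    support = m_lp > eps
    corr = np.ones_like(na_lp)
    corr[support] = na_lp[support] / m_lp[support]
    if settings.normalize_map:
        # rescale so the corrected image preserves the mean intensity within
        # the thresholded mask (the map then has approximately unit mean)
        scale = (data[mask] / corr[mask]).mean() / data[mask].mean()
        corr[support] *= scale
    log.info(
        "B1 correction: sigma1=%g size1=%d sigma2=%g size2=%d threshold=%s "
        "normalize_map=%s support=%d voxels",
        settings.sigma1, settings.size1, settings.sigma2, settings.size2,
        settings.threshold_method, settings.normalize_map, int(support.sum()),
    )

    corrected = data.copy()
    corrected[support] = data[support] / corr[support]
    out = image.with_data(corrected)
    map_img = image.with_data(corr)
    return out, map_img, support
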