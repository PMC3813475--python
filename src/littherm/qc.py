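"""Image-quality metrics for the monitoring series.

Dual-acquisition SNR, SNR = √2 · S₁ / SD₁₋₂, estimated in a small square ROI
of non-heated tissue from two repeated images: S₁ is the mean signal of the
first image over the ROI and SD₁₋₂ the standard deviation of their difference
(the √2 accounts for the doubled noise variance of a subtraction).  The
temperature standard deviation in non-heated liver quantifies the noise of
the reconstructed temperature maps; with uncorrelated complex noise it scales
as 1/SNR.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .prfs import SquareROI


def snr_dual(img1: np.ndarray, img2: np.ndarray, roi: SquareROI) -> float:
    """Dual-acquisition SNR in a square ROI (default use: 6×6 voxels).

    Accepts single 2D images or co-registered slice stacks ``(ns, ny, nx)``;
    stacks return the arithmetic mean of the per-slice SNRs.
    """
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("images must share a shape")
    if not roi.in_bounds(img1.shape):
        raise ValueError("ROI out of image bounds")
    rs, cs = roi.slices()
    if img1.ndim == 3:
        return float(
            np.mean([snr_dual(img1[s], img2[s], roi) for s in range(img1.shape[0])])
        )
    s1 = img1[rs, cs].mean()
    sd = (img1[rs, cs] - img2[rs, cs]).std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate subtraction: identical images in the ROI")
    return float(np.sqrt(2.0) * s1 / sd)


def temperature_sd(
    temp_map: np.ndarray,
    roi: SquareROI,
    lethal_mask: Optional[np.ndarray] = None,
) -> float:
    """Sample SD (ddof=1) of reconstructed temperature over a non-heated ROI.

    Warns when the ROI intersects a supplied lethal mask — the statistic is
    only meaningful in non-heated tissue.
    """
    temp_map = np.asarray(temp_map, dtype=float)
    if not roi.in_bounds(temp_map.shape):
        raise ValueError("ROI out of image bounds")
    rs, cs = roi.slices()
    if lethal_mask is not None and np.any(np.asarray(lethal_mask)[..., rs, cs]):
        warnings.warn("ROI intersects the lethal zone; SD is not a noise measure there",
                      stacklevel=2)
    return float(temp_map[..., rs, cs].std(ddof=1))
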