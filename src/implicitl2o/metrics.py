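"""Image-quality metrics used by the CT experiment."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim"]


def psnr(reference, estimate, peak=1.0):
    """``10 log10(peak^2 / MSE)`` in decibels; identical images give inf."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("psnr requires matching shapes")
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak ** 2 / mse)


def ssim(reference, estimate, peak=1.0):
    """Mean local SSIM with the standard 7x7 uniform window and constants
    C1=(0.01*peak)^2, C2=(0.03*peak)^2."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("ssim requires matching shapes")
    if min(ref.shape) < 7:
        raise ValueError("image smaller than the 7x7 SSIM window")
    return float(structural_similarity(ref, est, data_range=peak,
                                       win_size=7, gaussian_weights=False))
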