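"""Image-fidelity metrics: PSNR and single-scale SSIM."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "ssim", "PSNR_CAP_DB"]

#: Reported PSNR for identical images (MSE = 0).
PSNR_CAP_DB = 100.0


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(max_val^2 / MSE), in dB.

    Identical images return the 100 dB cap rather than infinity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(max_val**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity (Gaussian-weighted 11x11 window)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    kwargs = dict(gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False, data_range=data_range)
    if a.ndim == 3:
        kwargs["channel_axis"] = -1 if a.shape[-1] in (1, 3, 4) else 0
    return float(structural_similarity(a, b, **kwargs))
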