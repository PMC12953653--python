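"""Physics-constrained composite loss and differentiable image penalties.

The training objective combines four terms:

* GT-fidelity MSE between the restored output and the ground truth;
* the physics term — the restored output is pushed back through the *same*
  forward operators used to create the data (patch-wise convolution by the
  corrected PSF set, then 2x area downsampling) and compared against the
  degraded input, penalizing restorations the optics could not have produced;
* a (1 - MS-SSIM) structural term;
* anisotropic total variation.

All terms run on the autograd engine so the whole objective differentiates
end to end, including through the spectrum-corrected kernels inside the
physics term.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .forward_ops import downsample2x, patch_convolve

__all__ = ["physics_loss", "ms_ssim", "tv", "total_loss",
           "MS_SSIM_WEIGHTS", "gaussian_window"]

#: Standard 5-scale MS-SSIM exponents.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def physics_loss(x_hat, psf_set, y, tile: int, margin: int) -> Tensor:
    """MSE between the re-degraded restoration and the degraded input.

    ``x_hat`` is (3, 2H, 2W), ``y`` (3, H, W); ``psf_set`` is the sample's
    (corrected) kernel set indexed [tile_row][tile_col][channel]; ``tile``
    and ``margin`` must match the values used to degrade the sample, since
    the penalty is only meaningful under the identical forward operators.
    """
    x_hat, y = ag.as_tensor(x_hat), ag.as_tensor(y)
    if (x_hat.shape[-1] != 2 * y.shape[-1]
            or x_hat.shape[-2] != 2 * y.shape[-2]):
        raise ValueError("x_hat must be 2x the degraded input size")
    gr = len(psf_set)
    gc = len(psf_set[0])
    if gr * tile != x_hat.shape[-2] or gc * tile != x_hat.shape[-1]:
        raise ValueError(
            f"psf_set grid {(gr, gc)} with tile {tile} does not tile "
            f"x_hat {x_hat.shape[-2:]}")
    sim = downsample2x(patch_convolve(x_hat, psf_set, tile=tile, margin=margin))
    diff = sim - y
    return (diff * diff).mean()


def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    x = np.arange(size) - size // 2
    g = np.exp(-0.5 * (x / sigma) ** 2)
    w = np.outer(g, g)
    return w / w.sum()


def _ssim_cs(a: Tensor, b: Tensor, win: np.ndarray, c1: float, c2: float):
    """Mean SSIM and contrast-structure terms of two (C, H, W) images."""
    wt = Tensor(win)

    def filt(t: Tensor) -> Tensor:
        maps = [ag.conv2d_valid(t[c], wt) for c in range(t.shape[0])]
        return ag.concatenate(
            [m.reshape((1,) + m.shape) for m in maps], axis=0)

    mu_a, mu_b = filt(a), filt(b)
    mu_aa, mu_bb, mu_ab = mu_a * mu_a, mu_b * mu_b, mu_a * mu_b
    var_a = filt(a * a) - mu_aa
    var_b = filt(b * b) - mu_bb
    cov = filt(a * b) - mu_ab
    cs_map = (2.0 * cov + c2) / (var_a + var_b + c2)
    ssim_map = ((2.0 * mu_ab + c1) / (mu_aa + mu_bb + c1)) * cs_map
    return ssim_map.mean(), cs_map.mean()


def ms_ssim(a, b, levels: int = 5, window_size: int = 11,
            sigma: float = 1.5, data_range: float = 1.0) -> Tensor:
    """Multi-scale structural similarity of two (C, H, W) images in [0, 1].

    Standard construction: contrast-structure terms at the first
    ``levels - 1`` dyadic scales and full SSIM at the coarsest, combined with
    the standard exponents (renormalized when fewer than 5 levels are used).
    Raises if the image is smaller than the window at the coarsest scale.
    """
    a, b = ag.as_tensor(a), ag.as_tensor(b)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if not 1 <= levels <= len(MS_SSIM_WEIGHTS):
        raise ValueError(f"levels must be in [1, {len(MS_SSIM_WEIGHTS)}]")
    min_side = min(a.shape[-2:])
    if min_side < window_size * 2 ** (levels - 1):
        raise ValueError(
            f"image side {min_side} too small for {levels} levels with an "
            f"{window_size}px window")
    weights = np.asarray(MS_SSIM_WEIGHTS[:levels])
    weights = weights / weights.sum()
    win = gaussian_window(window_size, sigma)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2

    out = None
    for lv in range(levels):
        ssim_val, cs_val = _ssim_cs(a, b, win, c1, c2)
        term = ssim_val if lv == levels - 1 else cs_val
        term = term.relu() + 1e-12  # guard the fractional power
        factor = term ** float(weights[lv])
        out = factor if out is None else out * factor
        if lv < levels - 1:
            a, b = downsample2x(a), downsample2x(b)
    return out


def tv(a) -> Tensor:
    """Mean anisotropic total variation: mean|dx| + mean|dy| over valid diffs."""
    a = ag.as_tensor(a)
    dx = a[..., :, 1:] - a[..., :, :-1]
    dy = a[..., 1:, :] - a[..., :-1, :]
    return dx.abs().mean() + dy.abs().mean()


def total_loss(x_hat, gt, y, psf_set, weights, tile: int, margin: int,
               ssim_levels: int = 5):
    """Weighted composite loss; returns (total Tensor, per-term float dict).

    ``weights`` carries w_fid, w_phys, w_ssim, w_tv (see training module).
    """
    x_hat, gt, y = ag.as_tensor(x_hat), ag.as_tensor(gt), ag.as_tensor(y)
    if x_hat.shape != gt.shape:
        raise ValueError("x_hat and gt must share a shape")
    terms = {}
    diff = x_hat - gt
    fid = (diff * diff).mean()
    terms["fid"] = fid.item()
    total = weights.w_fid * fid
    if weights.w_phys > 0:
        phys = physics_loss(x_hat, psf_set, y, tile=tile, margin=margin)
        terms["phys"] = phys.item()
        total = total + weights.w_phys * phys
    else:
        terms["phys"] = 0.0
    if weights.w_ssim > 0:
        ssim_term = 1.0 - ms_ssim(x_hat, gt, levels=ssim_levels)
        terms["ssim"] = ssim_term.item()
        total = total + weights.w_ssim * ssim_term
    else:
        terms["ssim"] = 0.0
    if weights.w_tv > 0:
        tv_term = tv(x_hat)
        terms["tv"] = tv_term.item()
        total = total + weights.w_tv * tv_term
    else:
        terms["tv"] = 0.0
    terms["total"] = total.item()
    return total, terms
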