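"""Shared degradation operators: patch-wise convolution and area downsampling.

These operators define the image-formation model used in two places that must
agree exactly: the synthetic degradation pipeline (GT -> blurred -> noisy ->
downsampled input) and the physics term of the training loss (restored output
re-degraded and compared against the input).  They are written on the
autograd engine, so the loss path differentiates through them; the data
pipeline calls them on constant tensors.

Patch convolution handles the spatially-variant PSF: the image is tiled into
the dictionary's field cells, each tile is convolved with its own kernel on a
mirrored-extended support (margin + kernel half-width of true neighboring
content, mirrored only at the image boundary), and tiles are blended back
with linear overlap ramps over ``2*margin`` pixels so the blend weights sum
to one everywhere.  With a single uniform kernel the result equals plain
non-circular whole-image convolution away from the image boundary.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["patch_convolve", "downsample2x", "hwc_to_chw", "chw_to_hwc"]


def hwc_to_chw(img: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(np.asarray(img), -1, 0))


def chw_to_hwc(img: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(np.asarray(img), 0, -1))


def _blend_window(tile: int, margin: int, first: bool, last: bool) -> np.ndarray:
    """1D blend weights of length tile + 2*margin for one tile row/column."""
    n = tile + 2 * margin
    w = np.ones(n)
    if margin > 0:
        ramp = (np.arange(2 * margin) + 0.5) / (2 * margin)
        if not first:
            w[:2 * margin] = ramp
        if not last:
            w[-2 * margin:] = ramp[::-1]
    return w


def _mirror_indices(start: int, stop: int, n: int) -> np.ndarray:
    """Index range [start, stop) mirrored (reflect, no edge repeat) into [0, n)."""
    idx = np.arange(start, stop)
    period = 2 * (n - 1)
    idx = np.abs(np.mod(idx, period))
    return np.where(idx >= n, period - idx, idx)


def patch_convolve(x, kernels, tile: int, margin: int) -> Tensor:
    """Spatially-variant convolution of a (C, H, W) image by per-tile kernels.

    Parameters
    ----------
    x : Tensor or ndarray, shape (C, H, W)
    kernels : nested sequence indexed [tile_row][tile_col][channel], each a
        (k, k) Tensor or ndarray (odd k); gradients flow through Tensor
        kernels (used by the physics loss with corrected kernels).
    tile : tile side in pixels; must divide H and W.
    margin : overlap-blend half-width in pixels (ramps span 2*margin).
    """
    x = ag.as_tensor(x)
    c, h, w = x.shape
    if h % tile or w % tile:
        raise ValueError(f"tile {tile} must divide image {h}x{w}")
    gr, gc = h // tile, w // tile
    k0 = ag.as_tensor(kernels[0][0][0])
    khalf = k0.shape[-1] // 2
    if margin < 0:
        raise ValueError("margin must be non-negative")
    me = margin + khalf  # extraction margin: true content for exact conv

    chans = []
    for ci in range(c):
        xc = x[ci]
        out = None
        for i in range(gr):
            r0, r1 = i * tile, (i + 1) * tile
            ri = _mirror_indices(r0 - me, r1 + me, h)
            wy = _blend_window(tile, margin, i == 0, i == gr - 1)
            for j in range(gc):
                c0, c1 = j * tile, (j + 1) * tile
                cidx = _mirror_indices(c0 - me, c1 + me, w)
                ext = ag.gather2d(xc, ri, cidx)
                k = ag.as_tensor(kernels[i][j][ci])
                if k.shape[-1] % 2 != 1:
                    raise ValueError("kernels must have odd side")
                conv = ag.conv2d_valid(ext, k)  # (tile+2*margin)^2
                wx = _blend_window(tile, margin, j == 0, j == gc - 1)
                win = wy[:, None] * wx[None, :]
                # clip the tile's support to the image
                top = max(r0 - margin, 0)
                bot = min(r1 + margin, h)
                left = max(c0 - margin, 0)
                right = min(c1 + margin, w)
                sy = slice(top - (r0 - margin), bot - (r0 - margin))
                sx = slice(left - (c0 - margin), right - (c0 - margin))
                piece = conv[sy, sx] * win[sy, sx]
                emb = ag.pad_zero(piece, ((top, h - bot), (left, w - right)))
                out = emb if out is None else out + emb
        chans.append(out.reshape(1, h, w))
    return ag.concatenate(chans, axis=0)


def downsample2x(x) -> Tensor:
    """Factor-2 area (2x2 box) downsampling of a (C, H, W) image."""
    x = ag.as_tensor(x)
    c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("image sides must be even")
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
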