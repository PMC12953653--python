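"""Degradation-guided restoration head: PDFF, DGMSA, DGT and the 2x upsampler.

The restoration network consumes the Wiener front end's output and refines
it with transformer blocks that are *conditioned on the degradation*:

* PDFF (physical degradation feature fusion) pushes the PSF into the feature
  stream in the frequency domain — features are Fourier-transformed,
  modulated elementwise by the DC-normalized MTF of the sample's kernel
  (resampled to the feature scale), transformed back, concatenated with the
  originals and mixed by a pointwise layer;
* DGMSA is channel-transposed multi-head self-attention (queries, keys and
  values are per-channel descriptors over space, so cost is linear in pixel
  count) whose keys are modulated by a per-channel scale and bias predicted
  from the degradation features; the projection is zero-initialized, so at
  initialization DGMSA equals plain channel attention;
* DGT stacks norm -> DGMSA -> norm -> gated feed-forward with residuals;
* the output path is a sub-pixel (pixel-shuffle) 2x upsampler with a global
  residual from the bilinearly upsampled Wiener output, clipped to [0, 1] in
  eval mode.

A 3-scale encoder-decoder (scales 1, 1/2, 1/4) with skip connections carries
the blocks; the ``tiny`` profile stays under 300k parameters so the model is
CPU-trainable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor
from .calw import CALW, bin2x_kernel

__all__ = ["NetworkConfig", "PDFF", "DGMSA", "DGTBlock",
           "DegradationGuidedRestorer", "mtf_for_scale",
           "pixel_shuffle2", "pixel_unshuffle2"]

_PROFILES = {
    "tiny": dict(channels=(16, 32, 64), heads=(1, 2, 4), blocks=(1, 1, 1)),
    "base": dict(channels=(48, 96, 192), heads=(2, 4, 8), blocks=(2, 3, 3)),
}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture profile; the upsample factor is fixed at 2 (input h -> 2h)."""

    profile: str = "tiny"
    upsample: int = 2

    def __post_init__(self):
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.upsample != 2:
            raise ValueError("the output path is a fixed 2x upsampler")

    @property
    def channels(self):
        return _PROFILES[self.profile]["channels"]

    @property
    def heads(self):
        return _PROFILES[self.profile]["heads"]

    @property
    def blocks(self):
        return _PROFILES[self.profile]["blocks"]


def pixel_unshuffle2(x: Tensor) -> Tensor:
    c, h, w = x.shape
    t = x.reshape(c, h // 2, 2, w // 2, 2)
    return t.transpose((0, 2, 4, 1, 3)).reshape(4 * c, h // 2, w // 2)


def pixel_shuffle2(x: Tensor) -> Tensor:
    c4, h, w = x.shape
    c = c4 // 4
    t = x.reshape(c, 2, 2, h, w)
    return t.transpose((0, 3, 1, 4, 2)).reshape(c, 2 * h, 2 * w)


def mtf_for_scale(psf_set: np.ndarray, shape: tuple) -> np.ndarray:
    """DC-normalized MTF of the sample's mean input-grid kernel at a scale.

    The mean over field tiles and channels of the (GT-grid) PSF set is binned
    to the input grid, center-cropped if the scale is smaller than the kernel
    support, and embedded on the scale's grid; returns |FFT| / |FFT|(0).
    A delta kernel yields an all-ones MTF exactly.
    """
    mean_k = np.asarray(psf_set, dtype=float).mean(axis=(0, 1, 2))
    k = bin2x_kernel(mean_k).data
    ks = k.shape[0]
    h, w = shape
    side = min(ks, h if h % 2 else h - 1, w if w % 2 else w - 1)
    if side < ks:
        c, half = ks // 2, side // 2
        k = k[c - half:c + half + 1, c - half:c + half + 1]
        k = k / k.sum()
    grid = np.zeros(shape)
    grid[:k.shape[0], :k.shape[1]] = k
    m = np.abs(np.fft.fft2(grid))
    return m / m[0, 0]


class PDFF(nn.Module):
    """Frequency-domain fusion of the PSF's MTF into a feature map."""

    def __init__(self, channels: int, rng):
        self.mix = nn.Conv2d(2 * channels, channels, 1, rng)

    @staticmethod
    def modulate(feat: Tensor, mtf: np.ndarray) -> Tensor:
        """The modulated branch: IFFT( FFT(feat) * MTF ), shape-preserving."""
        if feat.shape[-2:] != mtf.shape:
            raise ValueError(
                f"feature {feat.shape[-2:]} vs MTF {mtf.shape} size mismatch")
        spec = ag.fft2(feat)
        mod = spec * Tensor(mtf[..., None])
        return ag.ifft2_real(mod)

    def __call__(self, feat: Tensor, mtf: np.ndarray) -> Tensor:
        branch = self.modulate(feat, mtf)
        return self.mix(ag.concatenate([feat, branch], axis=0))


class DGMSA(nn.Module):
    """Degradation-guided channel-transposed multi-head self-attention.

    Q/K/V are pointwise projections reshaped to (heads, C/heads, H*W) and
    L2-normalized along the spatial axis; attention is a (C/h x C/h) channel
    affinity with a learnable per-head temperature.  The degradation feature
    is pooled over space and mapped (zero-init) to a per-channel scale s and
    bias b applied to the keys: K' = K*(1+s) + b.
    """

    EPS = 1e-8

    def __init__(self, channels: int, heads: int, deg_channels: int, rng):
        if channels % heads:
            raise ValueError(f"heads {heads} must divide channels {channels}")
        self.channels, self.heads = channels, heads
        self.q = nn.Conv2d(channels, channels, 1, rng, bias=False)
        self.k = nn.Conv2d(channels, channels, 1, rng, bias=False)
        self.v = nn.Conv2d(channels, channels, 1, rng, bias=False)
        self.out = nn.Conv2d(channels, channels, 1, rng, bias=False)
        self.temperature = nn.Parameter(np.ones(heads))
        self.guide = nn.Linear(deg_channels, 2 * channels, rng, zero_init=True)

    def _split(self, t: Tensor, h: int, w: int) -> Tensor:
        ch = self.channels // self.heads
        return t.reshape(self.heads, ch, h * w)

    @staticmethod
    def _l2norm(t: Tensor) -> Tensor:
        norm = (t * t).sum(axis=-1, keepdims=True).sqrt()
        return t / (norm + DGMSA.EPS)

    def __call__(self, x: Tensor, deg: Tensor) -> Tensor:
        c, h, w = x.shape
        if deg.shape[-2:] != (h, w):
            raise ValueError("degradation features must match the input scale")
        pooled = deg.mean(axis=(1, 2))
        sb = self.guide(pooled)
        s, b = sb[:c], sb[c:]
        q = self._split(self.q(x), h, w)
        k = self._split(self.k(x), h, w)
        v = self._split(self.v(x), h, w)
        ch = self.channels // self.heads
        k = k * (1.0 + s.reshape(self.heads, ch, 1)) + b.reshape(self.heads, ch, 1)
        attn = ag.matmul(self._l2norm(q),
                         self._l2norm(k).transpose((0, 2, 1)))
        attn = ag.softmax(attn * self.temperature.reshape(self.heads, 1, 1),
                          axis=-1)
        out = ag.matmul(attn, v).reshape(c, h, w)
        return self.out(out)


class GatedFeedForward(nn.Module):
    """Pointwise gated feed-forward: conv -> (gelu gate * value) -> conv."""

    def __init__(self, channels: int, rng, expansion: int = 2):
        hidden = expansion * channels
        self.inp = nn.Conv2d(channels, 2 * hidden, 1, rng)
        self.outp = nn.Conv2d(hidden, channels, 1, rng)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        t = self.inp(x)
        a, b = t[:self.hidden], t[self.hidden:]
        return self.outp(ag.gelu(a) * b)


class DGTBlock(nn.Module):
    """Degradation-guided transformer block (pre-norm, residual)."""

    def __init__(self, channels: int, heads: int, deg_channels: int, rng):
        self.norm1 = nn.LayerNormChannel(channels)
        self.attn = DGMSA(channels, heads, deg_channels, rng)
        self.norm2 = nn.LayerNormChannel(channels)
        self.ffn = GatedFeedForward(channels, rng)

    def __call__(self, x: Tensor, deg: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x), deg)
        return x + self.ffn(self.norm2(x))


class DegradationGuidedRestorer(nn.Module):
    """CALW front end + 3-scale degradation-guided transformer + 2x upsampler."""

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        c1, c2, c3 = config.channels
        h1, h2, h3 = config.heads
        b1, b2, b3 = config.blocks

        self.calw = CALW(rng)
        self.shallow = nn.Conv2d(3, c1, 3, rng)
        self.pdff1 = PDFF(c1, rng)
        self.enc1 = [DGTBlock(c1, h1, c1, rng) for _ in range(b1)]
        self.down1 = nn.Conv2d(4 * c1, c2, 1, rng)
        self.pdff2 = PDFF(c2, rng)
        self.enc2 = [DGTBlock(c2, h2, c2, rng) for _ in range(b2)]
        self.down2 = nn.Conv2d(4 * c2, c3, 1, rng)
        self.pdff3 = PDFF(c3, rng)
        self.bottleneck = [DGTBlock(c3, h3, c3, rng) for _ in range(b3)]
        self.up2 = nn.Conv2d(c3, c2, 1, rng)
        self.fuse2 = nn.Conv2d(2 * c2, c2, 1, rng)
        self.dec2 = [DGTBlock(c2, h2, c2, rng) for _ in range(b2)]
        self.up1 = nn.Conv2d(c2, c1, 1, rng)
        self.fuse1 = nn.Conv2d(2 * c1, c1, 1, rng)
        self.dec1 = [DGTBlock(c1, h1, c1, rng) for _ in range(b1)]
        # zero-init: at initialization the model outputs exactly the
        # bilinearly upsampled Wiener restoration (residual learning)
        self.head = nn.Conv2d(c1, 12, 3, rng, zero_init=True)

    # -- forward ---------------------------------------------------------
    def __call__(self, y: Tensor, psf_set, training: bool = False):
        """Restore a degraded (3, H, W) image to (3, 2H, 2W).

        Returns (restored, calw_output).  In eval mode (training=False) the
        output is clipped to [0, 1].
        """
        _, h, w = y.shape
        if h % 4 or w % 4:
            raise ValueError("input sides must be divisible by 4")
        corrected = self.calw.corrected_psf_set(psf_set)
        base = self.calw(y, psf_set, corrected_set=corrected)

        psf_arr = np.asarray(psf_set, dtype=float) if not isinstance(
            psf_set, np.ndarray) else psf_set
        m1 = mtf_for_scale(psf_arr, (h, w))
        m2 = mtf_for_scale(psf_arr, (h // 2, w // 2))
        m3 = mtf_for_scale(psf_arr, (h // 4, w // 4))

        x = self.shallow(base)
        d1 = self.pdff1(x, m1)
        x = d1
        for blk in self.enc1:
            x = blk(x, d1)
        skip1 = x
        x = self.down1(pixel_unshuffle2(x))
        d2 = self.pdff2(x, m2)
        x = d2
        for blk in self.enc2:
            x = blk(x, d2)
        skip2 = x
        x = self.down2(pixel_unshuffle2(x))
        d3 = self.pdff3(x, m3)
        x = d3
        for blk in self.bottleneck:
            x = blk(x, d3)
        x = self.up2(ag.upsample2x_bilinear(x))
        x = self.fuse2(ag.concatenate([x, skip2], axis=0))
        for blk in self.dec2:
            x = blk(x, d2)
        x = self.up1(ag.upsample2x_bilinear(x))
        x = self.fuse1(ag.concatenate([x, skip1], axis=0))
        for blk in self.dec1:
            x = blk(x, d1)
        detail = pixel_shuffle2(self.head(x))
        out = detail + ag.upsample2x_bilinear(base)
        if not training:
            out = out.clip(0.0, 1.0)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite activation in output path")
        return out, base

    def restore(self, y_hwc: np.ndarray, psf_set) -> np.ndarray:
        """Numpy convenience wrapper: (H, W, 3) in, (2H, 2W, 3) out."""
        from .forward_ops import chw_to_hwc, hwc_to_chw
        with ag.no_grad():
            out, _ = self(Tensor(hwc_to_chw(y_hwc)), psf_set, training=False)
        return chw_to_hwc(out.data)

    def wiener_only(self, y_hwc: np.ndarray, psf_set) -> np.ndarray:
        """Bilinearly upsampled CALW output (the network's residual base)."""
        from .forward_ops import chw_to_hwc, hwc_to_chw
        with ag.no_grad():
            base = self.calw(Tensor(hwc_to_chw(y_hwc)), psf_set)
            up = ag.upsample2x_bilinear(base).clip(0.0, 1.0)
        return chw_to_hwc(up.data)
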