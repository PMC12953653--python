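"""Content-Adaptive Learnable Wiener (CALW) deconvolution front end.

The closed-form channel-wise Wiener filter, diagonalized in the Fourier
domain:

    x_hat = F^H [ conj(D_K) . F y / ( |D_K|^2 + e^{alpha_c} sum_d |D_{G_d}|^2 ) ]

where D_K is the (corrected) PSF spectrum, G_1..G_D a bank of regularization
kernels and alpha_c a learnable per-channel log-strength (c in {r, g, b} —
chromatic aberration makes the channel kernels differ, so each channel is
filtered independently).  Three pieces are learnable:

* ``alpha``        - per-channel regularization log-strengths,
* ``SpectrumCorrection`` - a small zero-initialized map that multiplies the
  PSF spectrum by a bounded real factor 1 + 0.5*tanh(.), absorbing kernel
  inaccuracies; at initialization the correction is the exact identity,
* ``RegKernelPredictor`` - predicts the D=8 regularization kernels as a fixed
  derivative-operator base bank plus a zero-initialized content-dependent
  residual from a shallow encoder on the degraded image.

The filter operates at input resolution on a mirrored 16 px pre-padded grid
(circular convolution algebra on the padded grid, center-cropped after) to
suppress wrap-around ringing.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from . import nn
from .autograd import Tensor

__all__ = [
    "SingularFilterError", "WienerContext", "base_reg_bank",
    "wiener_deconvolve", "SpectrumCorrection", "RegKernelPredictor", "CALW",
    "ALPHA_INIT", "WIENER_PAD",
]

ALPHA_INIT = math.log(1e-3)
WIENER_PAD = 16
N_REG_KERNELS = 8


class SingularFilterError(ZeroDivisionError):
    """Raised when the Wiener denominator vanishes at some frequency."""


def base_reg_bank() -> np.ndarray:
    """The fixed 3x3 regularization bank (D=8).

    First derivatives, Laplacian, four oriented second derivatives, and
    identity-minus-mean; all are zero-sum, so they regularize every non-DC
    frequency while leaving the mean intensity to the data term.
    """
    dx = np.array([[0, 0, 0], [0, -1, 1], [0, 0, 0]], dtype=float)
    dy = dx.T.copy()
    lap = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
    d2h = np.array([[0, 0, 0], [1, -2, 1], [0, 0, 0]], dtype=float)
    d2v = d2h.T.copy()
    d2d = np.array([[1, 0, 0], [0, -2, 0], [0, 0, 1]], dtype=float)
    d2a = np.array([[0, 0, 1], [0, -2, 0], [1, 0, 0]], dtype=float)
    imm = -np.full((3, 3), 1.0 / 9.0)
    imm[1, 1] += 1.0
    return np.stack([dx, dy, lap, d2h, d2v, d2d, d2a, imm])


def bin2x_kernel(kernel):
    """Resample a GT-grid kernel to the input grid by 2x2 sum binning.

    The forward model blurs at GT resolution and then area-downsamples by 2,
    so on the degraded input's grid the effective blur kernel is the 2x2
    binned kernel (sum-pooled: unit sum is preserved).  A (2m+1)-side kernel
    centered at m bins to an (m+1)-side kernel centered at m//2 when m is
    even, keeping the center on-grid.
    """
    k = ag.as_tensor(kernel)
    ks = k.shape[-1]
    pad = (-ks) % 2
    kp = ag.pad_zero(k, ((0, pad), (0, pad)))
    n = kp.shape[-1] // 2
    binned = kp.reshape(n, 2, n, 2).sum(axis=(1, 3))
    if n % 2 == 0:  # keep an odd side: pad one leading row/col of zeros
        binned = ag.pad_zero(binned, ((1, 0), (1, 0)))
    return binned


def _roll2d(x, sy: int, sx: int):
    """Circular shift of the last two axes (differentiable permutation)."""
    h, w = x.shape[-2], x.shape[-1]
    return ag.gather2d(x, np.roll(np.arange(h), sy), np.roll(np.arange(w), sx))


def kernel_otf(kernel, size: int):
    """Spectrum D_K of a centered (k, k) kernel embedded on a size^2 grid."""
    k = ag.as_tensor(kernel)
    ks = k.shape[-1]
    if ks > size:
        raise ValueError(f"kernel side {ks} exceeds grid {size}")
    padded = ag.pad_zero(k, ((0, size - ks), (0, size - ks)))
    return ag.fft2(_roll2d(padded, -(ks // 2), -(ks // 2)))


class WienerContext:
    """Per-channel OTFs, a regularization bank and log-strengths alpha.

    ``otf`` is (C, N, N, 2) stacked-complex, ``reg_bank`` (D, 3, 3) and
    ``alpha`` (C,); any of them may be autograd tensors.
    """

    def __init__(self, otf, reg_bank, alpha, image_size: int):
        self.otf = ag.as_tensor(otf)
        self.reg_bank = ag.as_tensor(reg_bank)
        self.alpha = ag.as_tensor(alpha)
        self.image_size = int(image_size)
        n = self.image_size
        if self.otf.shape[-3:] != (n, n, 2):
            raise ValueError("otf must be (..., N, N, 2) at the image size")
        # Unit-sum kernels give |D_K(0)| = 1; the bounded spectrum correction
        # can move it within [0.5, 1.5].  Anything outside flags a bad kernel.
        dc = np.hypot(self.otf.data[..., 0, 0, 0], self.otf.data[..., 0, 0, 1])
        if np.any((dc < 0.5 - 1e-6) | (dc > 1.5 + 1e-6)):
            raise ValueError(
                "OTF zero-frequency magnitude outside [0.5, 1.5]; "
                "kernels must be (corrected) unit-sum")

    @classmethod
    def from_kernels(cls, kernels, image_size: int, reg_bank=None, alpha=None):
        """Build a context from (C, k, k) centered kernels."""
        kernels = [ag.as_tensor(k) for k in kernels]
        otfs = [kernel_otf(k, image_size) for k in kernels]
        otf = ag.concatenate([o.reshape((1,) + o.shape) for o in otfs], axis=0)
        if reg_bank is None:
            reg_bank = base_reg_bank()
        if alpha is None:
            alpha = np.full(len(kernels), ALPHA_INIT)
        return cls(otf, reg_bank, alpha, image_size)

    def reg_power(self) -> Tensor:
        """sum_d |D_{G_d}|^2 on the image grid (N, N)."""
        n = self.image_size
        g = self.reg_bank
        d, ks = g.shape[0], g.shape[-1]
        padded = ag.pad_zero(g, ((0, n - ks), (0, n - ks)))
        return ag.complex_abs2(ag.fft2(padded)).sum(axis=0)


def wiener_deconvolve(y, ctx: WienerContext, channel: int) -> Tensor:
    """Eq.-form Wiener deconvolution of one channel on its own grid.

    ``y`` is the (N, N) degraded channel; the convolution convention is
    circular (periodic) on this grid.  Returns the real restored channel.
    """
    y = ag.as_tensor(y)
    n = ctx.image_size
    if y.shape != (n, n):
        raise ValueError(f"image {y.shape} does not match context size {n}")
    dk = ctx.otf[channel]
    s = ctx.reg_power()
    denom = ag.complex_abs2(dk) + ctx.alpha[channel].exp() * s
    if float(denom.data.min()) <= 1e-300:
        raise SingularFilterError(
            "Wiener denominator vanishes (zero OTF and zero regularization "
            "at some frequency)")
    numer = ag.complex_mul(ag.complex_conj(dk), ag.fft2(y))
    ratio = numer / denom.reshape(n, n, 1)
    return ag.ifft2_real(ratio)


class SpectrumCorrection(nn.Module):
    """Bounded multiplicative PSF-spectrum correction, identity at init.

    Operates on the stacked real/imag planes of a kernel's spectrum through
    two pointwise layers; the output scalar field g is squashed to
    (-0.5, 0.5) and applied as ``corrected = otf * (1 + g)``, so the DC
    magnitude stays within [0.5, 1.5] by construction.
    """

    def __init__(self, rng, hidden: int = 8):
        self.enc = nn.Conv2d(2, hidden, 1, rng)
        self.head = nn.Conv2d(hidden, 1, 1, rng, zero_init=True)

    def __call__(self, otf: Tensor) -> Tensor:
        """Correct a stacked-complex spectrum (n, n, 2) -> (n, n, 2)."""
        if otf.shape[-1] != 2 or otf.ndim != 3:
            raise ValueError("otf must be (n, n, 2) stacked-complex")
        planes = otf.transpose((2, 0, 1))  # (2, n, n)
        g = 0.5 * self.head(self.enc(planes).relu()).tanh()  # (1, n, n)
        factor = 1.0 + g.transpose((1, 2, 0))  # (n, n, 1)
        return otf * factor

    def correct_kernel(self, kernel) -> Tensor:
        """Apply the spectrum correction to a centered spatial kernel."""
        k = ag.as_tensor(kernel)
        corrected = self(ag.fft2(k))
        return ag.ifft2_real(corrected)


class RegKernelPredictor(nn.Module):
    """Content-adaptive regularization kernels: base bank + learned residual.

    A shallow encoder pools the degraded RGB image into a descriptor from
    which a zero-initialized head predicts additive 3x3 residuals for each of
    the D base kernels, so at initialization the output equals the base bank
    exactly.
    """

    def __init__(self, rng, hidden: int = 8, n_kernels: int = N_REG_KERNELS):
        self.n_kernels = n_kernels
        self.base = base_reg_bank()[:n_kernels]
        self.enc = nn.Conv2d(3, hidden, 3, rng)
        self.head = nn.Linear(hidden, n_kernels * 9, rng, zero_init=True)

    def __call__(self, y: Tensor) -> Tensor:
        """Predict (D, 3, 3) kernels from the degraded (3, H, W) image."""
        feat = self.enc(y).relu().mean(axis=(1, 2))  # (hidden,)
        resid = self.head(feat).reshape(self.n_kernels, 3, 3)
        return Tensor(self.base) + resid


class CALW(nn.Module):
    """The full learnable Wiener front end.

    ``__call__`` takes the degraded (3, H, W) image and the sample's PSF set
    (tile_rows, tile_cols, 3, k, k); per channel it corrects each tile
    kernel's spectrum, averages the corrected kernels across the field window
    into the channel's deconvolution kernel, predicts the regularization bank
    from the image content once, and applies the Wiener filter on a mirrored
    ``pad``-extended grid.  Returns the restoration at input resolution.
    """

    def __init__(self, rng, pad: int = WIENER_PAD):
        self.pad = pad
        self.alpha = nn.Parameter(np.full(3, ALPHA_INIT))
        self.correction = SpectrumCorrection(rng)
        self.predictor = RegKernelPredictor(rng)

    def corrected_psf_set(self, psf_set):
        """Per-tile, per-channel corrected kernels as a nested Tensor list."""
        gr, gc = np.asarray(psf_set).shape[:2] if not isinstance(
            psf_set, (list, tuple)) else (len(psf_set), len(psf_set[0]))
        out = []
        for i in range(gr):
            row = []
            for j in range(gc):
                row.append([self.correction.correct_kernel(psf_set[i][j][c])
                            for c in range(3)])
            out.append(row)
        return out

    def channel_kernels(self, corrected_set):
        """Field-window average of the corrected kernels, one per channel."""
        gr, gc = len(corrected_set), len(corrected_set[0])
        chans = []
        for c in range(3):
            acc = None
            for i in range(gr):
                for j in range(gc):
                    k = corrected_set[i][j][c]
                    acc = k if acc is None else acc + k
            chans.append(acc * (1.0 / (gr * gc)))
        return chans

    def __call__(self, y: Tensor, psf_set, corrected_set=None) -> Tensor:
        c, h, w = y.shape
        if c != 3:
            raise ValueError("expected a (3, H, W) image")
        if h != w:
            raise ValueError("square inputs expected")
        if corrected_set is None:
            corrected_set = self.corrected_psf_set(psf_set)
        # Dictionary kernels live on the GT grid; the Wiener filter runs on
        # the 2x-downsampled input grid, so bin the kernels to that grid.
        kernels = [bin2x_kernel(k) for k in self.channel_kernels(corrected_set)]
        n = h + 2 * self.pad
        reg = self.predictor(y)
        ctx = WienerContext.from_kernels(kernels, n, reg_bank=reg,
                                         alpha=self.alpha)
        outs = []
        for ci in range(3):
            ypad = ag.reflect_pad2d(y[ci], self.pad)
            x = wiener_deconvolve(ypad, ctx, ci)
            x = x[self.pad:self.pad + h, self.pad:self.pad + w]
            outs.append(x.reshape(1, h, w))
        return ag.concatenate(outs, axis=0)
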