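"""Minimal neural-network layers on top of the autograd engine.

Layout convention is channel-first without a batch axis: feature maps are
(C, H, W) tensors; training loops average gradients over samples explicitly.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "LayerNormChannel", "Linear"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state (de)serialization."""

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, "
                             f"unexpected={sorted(extra)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=float).copy()


class Conv2d(Module):
    """2D convolution (cross-correlation), stride 1, zero 'same' padding.

    Weight is stored flat as (out_ch, kh*kw*in_ch) with (dy, dx, ci) minor
    order; the forward pass is built from pad/slice/concat/matmul primitives
    so it differentiates without a dedicated conv kernel.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng,
                 bias: bool = True, zero_init: bool = False):
        if ksize % 2 != 1:
            raise ValueError("ksize must be odd")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        fan_in = in_ch * ksize * ksize
        if zero_init:
            w = np.zeros((out_ch, fan_in))
        else:
            w = rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k = self.ksize
        if k == 1:
            cols = x.reshape(c, h * w)
        else:
            p = k // 2
            xp = ag.pad_zero(x, ((p, p), (p, p)))
            shifts = []
            for dy in range(k):
                for dx in range(k):
                    shifts.append(xp[:, dy:dy + h, dx:dx + w])
            cols = ag.concatenate(shifts, axis=0).reshape(k * k * c, h * w)
        out = ag.matmul(self.weight, cols).reshape(self.out_ch, h, w)
        if self.bias is not None:
            out = out + self.bias.reshape(self.out_ch, 1, 1)
        return out


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng, zero_init: bool = False):
        if zero_init:
            w = np.zeros((out_f, in_f))
        else:
            w = rng.standard_normal((out_f, in_f)) * np.sqrt(1.0 / in_f)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_f))

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 1:
            out = ag.matmul(self.weight, x.reshape(-1, 1)) + self.bias.reshape(-1, 1)
            return out.reshape(-1)
        return ag.matmul(self.weight, x) + self.bias.reshape(
            (-1,) + (1,) * (x.ndim - 1))


class LayerNormChannel(Module):
    """Per-pixel layer normalization over the channel axis of (C, H, W)."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=0, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        c = x.shape[0]
        return xn * self.gamma.reshape(c, 1, 1) + self.beta.reshape(c, 1, 1)
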