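"""A compact reverse-mode automatic differentiation engine on numpy arrays.

The learnable parts of the restoration pipeline (Wiener strengths, spectrum
correction, attention network) need gradients of image-domain and
frequency-domain operators.  This module provides a ``Tensor`` wrapping a
float64 ndarray with a dynamically built computation graph and
vector-Jacobian products for the primitives the pipeline uses:

* elementwise arithmetic, exp/tanh/sqrt/relu/clip with broadcasting,
* matmul (batched), reductions, reshape/transpose/concatenate/slicing,
* zero padding, index gathering (used for reflective padding),
* 2D FFT of a real array and real part of the inverse FFT — complex values
  travel as a trailing axis of size 2 (re, im), so Wiener filtering is plain
  real arithmetic on stacked planes,
* valid-mode 2D convolution (true convolution, differentiable in both image
  and kernel),
* factor-2 bilinear upsampling (exact adjoint via its separable weight
  matrices).

Gradients are accumulated by topological traversal.  ``Tensor``s without
``requires_grad`` act as constants, so forward-model code can share these
operators at negligible cost.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "Tensor", "as_tensor", "no_grad", "concatenate", "matmul", "fft2", "ifft2_real",
    "conv2d_valid", "pad_zero", "gather2d", "upsample2x_bilinear",
    "softmax", "gelu", "complex_mul", "complex_abs2", "complex_conj",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (fast inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "requires_grad", "grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from absorbing our operators

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- basic properties ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            def backward(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / other.data**2)
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data**p, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data**(p - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    # -- elementwise functions -------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor._make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * val)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor._make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - val**2))
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor._make(val, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor._make(np.abs(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * sign)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor._make(np.clip(self.data, lo, hi), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                           (self,), None)
        if out.requires_grad:
            shape = self.data.shape

            def backward(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
                self._accum(np.broadcast_to(g, shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in
             (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)
        if out.requires_grad:
            shape = self.data.shape

            def backward(g):
                full = np.zeros(shape)
                full[idx] = g  # basic indexing: no repeated targets
                self._accum(full)
            out._backward = backward
        return out

    def max(self, axis=None, keepdims=False) -> np.ndarray:
        """Detached maximum (used for numerically stable softmax)."""
        return self.data.max(axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor._make(a.data @ b.data, (a, b), None)
    if out.requires_grad:
        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2),
                                      a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g,
                                      b.data.shape))
        out._backward = backward
    return out


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                       tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = backward
    return out


def pad_zero(x, pad: tuple) -> Tensor:
    """Zero-pad the last two axes by ((top, bottom), (left, right))."""
    x = as_tensor(x)
    (pt, pb), (pl, pr) = pad
    width = [(0, 0)] * (x.ndim - 2) + [(pt, pb), (pl, pr)]
    out = Tensor._make(np.pad(x.data, width), (x,), None)
    if out.requires_grad:
        h, w = x.shape[-2:]
        sl = (Ellipsis, slice(pt, pt + h), slice(pl, pl + w))
        out._backward = lambda g: x._accum(g[sl])
    return out


def gather2d(x, row_idx: np.ndarray, col_idx: np.ndarray) -> Tensor:
    """Index the last two axes by outer-product index vectors.

    Serves as reflective/replicate padding when the index vectors repeat
    entries; the adjoint scatter-adds into the repeated sources.
    """
    x = as_tensor(x)
    row_idx = np.asarray(row_idx, dtype=int)
    col_idx = np.asarray(col_idx, dtype=int)
    val = x.data[..., row_idx[:, None], col_idx[None, :]]
    out = Tensor._make(val, (x,), None)
    if out.requires_grad:
        shape = x.data.shape

        def backward(g):
            full = np.zeros(shape)
            flat = full.reshape(-1, shape[-2], shape[-1])
            gf = g.reshape(-1, len(row_idx), len(col_idx))
            b = np.arange(flat.shape[0])[:, None, None]
            np.add.at(flat, (b, row_idx[None, :, None], col_idx[None, None, :]), gf)
            x._accum(full)
        out._backward = backward
    return out


def reflect_pad2d(x, pad: int) -> Tensor:
    """Mirror padding (no edge repeat) on the last two axes."""
    x = as_tensor(x)
    h, w = x.shape[-2:]
    ri = np.pad(np.arange(h), pad, mode="reflect")
    ci = np.pad(np.arange(w), pad, mode="reflect")
    return gather2d(x, ri, ci)


def fft2(x) -> Tensor:
    """2D FFT over the last two axes of a real tensor -> (..., H, W, 2)."""
    x = as_tensor(x)
    c = np.fft.fft2(x.data, axes=(-2, -1))
    out = Tensor._make(np.stack([c.real, c.imag], axis=-1), (x,), None)
    if out.requires_grad:
        n = x.shape[-2] * x.shape[-1]

        def backward(g):
            gc = g[..., 0] + 1j * g[..., 1]
            x._accum(np.real(np.fft.ifft2(gc, axes=(-2, -1))) * n)
        out._backward = backward
    return out


def ifft2_real(c) -> Tensor:
    """Real part of the 2D inverse FFT of a stacked-complex tensor."""
    c = as_tensor(c)
    z = c.data[..., 0] + 1j * c.data[..., 1]
    out = Tensor._make(np.real(np.fft.ifft2(z, axes=(-2, -1))), (c,), None)
    if out.requires_grad:
        n = out.shape[-2] * out.shape[-1]

        def backward(g):
            u = np.fft.fft2(g, axes=(-2, -1)) / n
            c._accum(np.stack([u.real, u.imag], axis=-1))
        out._backward = backward
    return out


def complex_mul(a, b) -> Tensor:
    """Product of stacked-complex tensors (..., 2)."""
    ar, ai = a[..., 0], a[..., 1]
    br, bi = b[..., 0], b[..., 1]
    re = ar * br - ai * bi
    im = ar * bi + ai * br
    return concatenate([re.reshape(re.shape + (1,)),
                        im.reshape(im.shape + (1,))], axis=-1)


def complex_conj(a) -> Tensor:
    re, im = a[..., 0], a[..., 1]
    return concatenate([re.reshape(re.shape + (1,)),
                        (-im).reshape(im.shape + (1,))], axis=-1)


def complex_abs2(a) -> Tensor:
    return a[..., 0] ** 2 + a[..., 1] ** 2


def conv2d_valid(x, k) -> Tensor:
    """True 2D convolution, valid mode, differentiable in image and kernel."""
    x, k = as_tensor(x), as_tensor(k)
    out = Tensor._make(fftconvolve(x.data, k.data, mode="valid"), (x, k), None)
    if out.requires_grad:
        def backward(g):
            if x.requires_grad:
                x._accum(fftconvolve(g, k.data[::-1, ::-1], mode="full"))
            if k.requires_grad:
                gk = fftconvolve(x.data, g[::-1, ::-1], mode="valid")
                k._accum(gk[::-1, ::-1])
        out._backward = backward
    return out


def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n, n) factor-2 bilinear interpolation matrix (half-pixel centers)."""
    w = np.zeros((2 * n, n))
    for i in range(2 * n):
        p = (i + 0.5) / 2.0 - 0.5
        j0 = int(math.floor(p))
        t = p - j0
        j0c = min(max(j0, 0), n - 1)
        j1c = min(max(j0 + 1, 0), n - 1)
        w[i, j0c] += 1.0 - t
        w[i, j1c] += t
    return w


_BILINEAR_CACHE: dict = {}


def upsample2x_bilinear(x) -> Tensor:
    """Factor-2 bilinear upsampling of the last two axes."""
    x = as_tensor(x)
    h, w = x.shape[-2:]
    for n in (h, w):
        if n not in _BILINEAR_CACHE:
            _BILINEAR_CACHE[n] = _bilinear_matrix(n)
    wh, ww = _BILINEAR_CACHE[h], _BILINEAR_CACHE[w]
    val = (wh @ x.data) @ ww.T
    out = Tensor._make(val, (x,), None)
    if out.requires_grad:
        out._backward = lambda g: x._accum((wh.T @ g) @ ww)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x) -> Tensor:
    """Gaussian error linear unit (tanh approximation), fused primitive."""
    x = as_tensor(x)
    d = x.data
    u = _GELU_C * (d + 0.044715 * d**3)
    t = np.tanh(u)
    out = Tensor._make(0.5 * d * (1.0 + t), (x,), None)
    if out.requires_grad:
        du = _GELU_C * (1.0 + 3 * 0.044715 * d * d)
        deriv = 0.5 * (1.0 + t) + 0.5 * d * (1.0 - t * t) * du
        out._backward = lambda g: x._accum(g * deriv)
    return out
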