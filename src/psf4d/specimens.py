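"""Procedural phantom specimens standing in for captured ground-truth images.

Four styles emulate the content classes a zoom-microscope sees:

* ``texture``  - band-limited colored noise (tissue-like broadband texture),
* ``cells``    - Poisson-disk packed elliptical blobs with darker membranes
                 on a bright background (stained cell fields),
* ``grating``  - sinusoidal gratings of known frequency (contrast targets),
* ``usaf``     - bar triplets whose widths follow the USAF-1951 geometric
                 progression (adjacent elements scale by 2**(1/6)).

All styles are deterministic for a fixed (seed, style) and return RGB pixel
values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpecimenImage", "generate_specimen", "usaf_bar_width", "STYLES"]

STYLES = ("texture", "cells", "grating", "usaf")


@dataclass
class SpecimenImage:
    """A ground-truth phantom: (size, size, 3) float array in [0, 1]."""

    pixels: np.ndarray
    style: str
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = p

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def usaf_bar_width(group: int, element: int, base_px: float = 64.0) -> float:
    """Bar width (px) of a USAF-1951 element: base / 2**(group + (element-1)/6).

    Adjacent elements within a group are spaced by the sixth root of two;
    frequency doubles every group (MIL-STD-150A geometry).
    """
    return base_px / 2.0 ** (group + (element - 1) / 6.0)


def _colored_noise(rng: np.random.Generator, size: int, slope: float = 1.6):
    white = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size)
    fr = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    fr[0, 0] = fr[0, 1]
    spec = np.fft.fft2(white) * fr ** (-slope / 2.0)
    img = np.real(np.fft.ifft2(spec))
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


def _texture(rng: np.random.Generator, size: int) -> np.ndarray:
    luma = _colored_noise(rng, size)
    out = np.empty((size, size, 3))
    for c in range(3):
        chroma = _colored_noise(rng, size)
        out[..., c] = 0.7 * luma + 0.3 * chroma
    return 0.05 + 0.9 * np.clip(out, 0.0, 1.0)


def _poisson_disk(rng: np.random.Generator, size: int, radius: float,
                  n_attempts: int = 3000) -> np.ndarray:
    pts: list = []
    for _ in range(n_attempts):
        p = rng.uniform(0, size, 2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= radius**2 for q in pts):
            pts.append(p)
    return np.asarray(pts)


def _cells(rng: np.random.Generator, size: int) -> np.ndarray:
    bg = 0.82 + 0.06 * _colored_noise(rng, size)
    img = np.stack([bg * 0.98, bg * 0.95, bg], axis=-1)
    r_mean = max(6.0, size / 18.0)
    centers = _poisson_disk(rng, size, radius=2.2 * r_mean)
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx in centers:
        a = r_mean * rng.uniform(0.6, 1.4)
        b = r_mean * rng.uniform(0.6, 1.4)
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        interior = d < 1.0
        membrane = (d >= 0.82) & (d < 1.0)
        tint = rng.uniform(0.45, 0.75)
        img[interior] *= np.array([tint, tint * 0.8, tint * 1.05])
        img[membrane] *= 0.55
        # nucleus
        nucleus = d < rng.uniform(0.25, 0.4)
        img[nucleus] *= np.array([0.6, 0.5, 0.85])
    return np.clip(img, 0.0, 1.0)


def _grating(rng: np.random.Generator, size: int, freq: float = None,
             angle: float = 0.0) -> np.ndarray:
    if freq is None:
        freq = float(rng.integers(6, size // 8))
    yy, xx = np.mgrid[0:size, 0:size]
    phase = 2 * np.pi * freq * (np.cos(angle) * xx + np.sin(angle) * yy) / size
    g = 0.5 + 0.45 * np.sin(phase)
    rgb = np.stack([g, g, g], axis=-1)
    tint = 0.9 + 0.1 * rng.uniform(0, 1, 3)
    return np.clip(rgb * tint, 0.0, 1.0)


def _usaf(rng: np.random.Generator, size: int) -> np.ndarray:
    img = np.full((size, size, 3), 0.92)
    base = size / 8.0
    y = int(0.06 * size)
    group, element = 0, 1
    while y < size - base:
        w = usaf_bar_width(group, element, base_px=base)
        if w < 1.5:
            break
        bar_len = int(5 * w)
        x = int(0.06 * size)
        # three horizontal bars
        for b in range(3):
            y0 = int(y + 2 * b * w)
            img[y0:int(y0 + w), x:x + bar_len] = 0.05
        # three vertical bars to the right
        x2 = x + bar_len + int(2 * w)
        for b in range(3):
            x0 = int(x2 + 2 * b * w)
            img[int(y):int(y + 5 * w), x0:int(x0 + w)] = 0.05
        y = int(y + 6 * w + max(2, 0.02 * size))
        element += 1
        if element > 6:
            element, group = 1, group + 1
    return img


def generate_specimen(seed: int, size: int = 512, style: str = "texture",
                      **style_kwargs) -> SpecimenImage:
    """Render a deterministic phantom specimen.

    ``style_kwargs`` are forwarded to the style renderer (e.g. ``freq`` and
    ``angle`` for gratings).
    """
    if size % 2:
        raise ValueError("size must be even")
    if style not in STYLES:
        raise ValueError(f"unknown style {style!r}; choose from {STYLES}")
    rng = np.random.default_rng(seed)
    if style == "texture":
        pixels = _texture(rng, size)
    elif style == "cells":
        pixels = _cells(rng, size)
    elif style == "grating":
        pixels = _grating(rng, size, **style_kwargs)
    else:
        pixels = _usaf(rng, size)
    return SpecimenImage(pixels=pixels, style=style, seed=seed)
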