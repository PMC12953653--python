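"""The 4D PSF dictionary: (zoom level, field row, field col, wavelength).

A dictionary stores one normalized blur kernel per combination of zoom level,
field cell (sensor tiled into patches, 8x6 = 48 cells at the default
2048x1536 / 256 px geometry) and wavelength channel.  Lookup maps a sensor
pixel to its field cell (half-open tiling, 0-based, origin top-left) and a
continuous magnification to the nearest stored zoom level (ties break to the
lower level).  Kernels are stored unmodified; users needing kernels at an
unstored magnification should re-render via the pupil model rather than
interpolate, since kernel interpolation is not energy-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .pupil import (
    DEFAULT_PATCH_SIZE,
    DEFAULT_SENSOR_SHAPE,
    DEFAULT_WAVELENGTHS_UM,
    CHANNEL_WAVELENGTH_UM,
    SENSOR_PIXEL_UM,
    PSFKernel,
    PupilModel,
    grid_shape,
    render_psf,
)

__all__ = [
    "PSFDictionary",
    "DictionaryFormatError",
    "build_dictionary",
    "save_dictionary",
    "load_dictionary",
    "mtf",
    "rgb_wavelength_index",
]

_REQUIRED_ATTRS = ("zoom_levels", "wavelengths_um", "sensor_shape",
                   "patch_size", "sampling_um")


class DictionaryFormatError(ValueError):
    """Raised when a dictionary file lacks required structure or attributes."""


def rgb_wavelength_index(channel: int,
                         wavelengths=DEFAULT_WAVELENGTHS_UM) -> int:
    """Wavelength index serving an RGB channel (R=656 nm, G=588, B=486)."""
    wl = CHANNEL_WAVELENGTH_UM[channel]
    return int(np.argmin(np.abs(np.asarray(wavelengths) - wl)))


@dataclass
class PSFDictionary:
    """4D-indexed bank of normalized PSF kernels.

    ``kernels`` has shape (levels, rows, cols, wavelengths, k, k); indexing is
    0-based with the field origin at the sensor's top-left patch.
    """

    kernels: np.ndarray
    zoom_levels: tuple
    wavelengths: tuple = DEFAULT_WAVELENGTHS_UM
    sensor_shape: tuple = DEFAULT_SENSOR_SHAPE
    patch_size: int = DEFAULT_PATCH_SIZE
    sampling_um: float = SENSOR_PIXEL_UM
    captured_energy: np.ndarray = None

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        if self.kernels.ndim != 6:
            raise ValueError("kernels must be 6D (L, R, C, W, k, k)")
        rows, cols = grid_shape(self.sensor_shape, self.patch_size)
        L, R, C, W = self.kernels.shape[:4]
        if (R, C) != (rows, cols):
            raise ValueError(
                f"kernel grid {(R, C)} does not match sensor tiling {(rows, cols)}")
        if L != len(self.zoom_levels) or W != len(self.wavelengths):
            raise ValueError("kernel axes disagree with level/wavelength lists")
        self.zoom_levels = tuple(float(b) for b in self.zoom_levels)
        self.wavelengths = tuple(float(w) for w in self.wavelengths)

    @property
    def grid(self) -> tuple:
        return self.kernels.shape[1:3]

    @property
    def kernel_size(self) -> int:
        return self.kernels.shape[-1]

    def __len__(self) -> int:
        return int(np.prod(self.kernels.shape[:4]))

    def validate(self, tol: float = 1e-6) -> None:
        """Assert every kernel is non-negative and unit-sum within tol."""
        if np.any(self.kernels < 0):
            raise ValueError("dictionary contains negative kernel entries")
        sums = self.kernels.sum(axis=(-2, -1))
        worst = float(np.abs(sums - 1.0).max())
        if worst > tol:
            raise ValueError(f"kernel sums deviate from 1 by up to {worst:g}")

    def nearest_level_index(self, beta: float) -> int:
        """Nearest stored zoom level; exact midpoints resolve to the lower level."""
        levels = np.asarray(self.zoom_levels)
        return int(np.argmin(np.abs(levels - beta)))

    def cell_of_pixel(self, pixel_rc: tuple) -> tuple:
        row_px, col_px = pixel_rc
        h, w = self.sensor_shape
        if not (0 <= row_px < h and 0 <= col_px < w):
            raise IndexError(f"pixel {pixel_rc} outside sensor {self.sensor_shape}")
        rows, cols = self.grid
        return (min(int(row_px) // self.patch_size, rows - 1),
                min(int(col_px) // self.patch_size, cols - 1))

    def lookup(self, beta: float, pixel_rc: tuple, channel: int) -> PSFKernel:
        """Kernel for a magnification, sensor pixel and wavelength channel."""
        if not 0 <= channel < len(self.wavelengths):
            raise IndexError(f"wavelength channel {channel} out of range")
        li = self.nearest_level_index(beta)
        cell = self.cell_of_pixel(pixel_rc)
        k = self.kernels[li, cell[0], cell[1], channel]
        return PSFKernel(kernel=k, beta=self.zoom_levels[li], field_rc=cell,
                         wavelength_um=self.wavelengths[channel])

    def cell_kernel(self, beta: float, cell: tuple, channel: int) -> np.ndarray:
        """Raw kernel array for a field cell (bypasses the pixel mapping)."""
        li = self.nearest_level_index(beta)
        return self.kernels[li, cell[0], cell[1], channel]


def build_dictionary(pupil: PupilModel = None,
                     sensor_shape: tuple = DEFAULT_SENSOR_SHAPE,
                     patch_size: int = DEFAULT_PATCH_SIZE,
                     zoom_levels=(10.0, 20.0, 40.0, 60.0, 80.0, 100.0),
                     wavelengths=None, kernel_size: int = 33,
                     pad: int = 512, min_energy: float = 0.5,
                     progress: bool = False) -> PSFDictionary:
    """Render every (level, row, col, wavelength) kernel into a dictionary."""
    if pupil is None:
        pupil = PupilModel()
    if wavelengths is None:
        wavelengths = pupil.wavelengths
    zoom_levels = tuple(zoom_levels)
    if not zoom_levels:
        raise ValueError("zoom_levels must be non-empty")
    rows, cols = grid_shape(sensor_shape, patch_size)
    out = np.empty((len(zoom_levels), rows, cols, len(wavelengths),
                    kernel_size, kernel_size))
    energy = np.empty(out.shape[:4])
    it = enumerate(zoom_levels)
    for li, beta in it:
        for r in range(rows):
            for c in range(cols):
                for wi, wl in enumerate(wavelengths):
                    k = render_psf(pupil, beta, (r, c), wl,
                                   grid=(rows, cols), pad=pad,
                                   kernel_size=kernel_size,
                                   min_energy=min_energy,
                                   sensor_shape=sensor_shape)
                    out[li, r, c, wi] = k.kernel
                    energy[li, r, c, wi] = k.captured_energy
        if progress:
            print(f"rendered zoom level {beta:g}x "
                  f"({(li + 1) * rows * cols * len(wavelengths)} kernels)")
    return PSFDictionary(kernels=out, zoom_levels=zoom_levels,
                         wavelengths=tuple(wavelengths),
                         sensor_shape=tuple(sensor_shape),
                         patch_size=patch_size, captured_energy=energy)


def save_dictionary(d: PSFDictionary, path) -> None:
    """Write the dictionary to an HDF5 container (one 6D dataset + attrs)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("kernels", data=d.kernels)
        ds.attrs["axes"] = "level,row,col,channel,ky,kx"
        f.attrs["zoom_levels"] = np.asarray(d.zoom_levels)
        f.attrs["wavelengths_um"] = np.asarray(d.wavelengths)
        f.attrs["sensor_shape"] = np.asarray(d.sensor_shape)
        f.attrs["patch_size"] = int(d.patch_size)
        f.attrs["sampling_um"] = float(d.sampling_um)
        if d.captured_energy is not None:
            f.create_dataset("captured_energy", data=d.captured_energy)


def load_dictionary(path) -> PSFDictionary:
    """Load a dictionary, validating schema; missing attributes are named."""
    with h5py.File(path, "r") as f:
        if "kernels" not in f:
            raise DictionaryFormatError("missing dataset 'kernels'")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise DictionaryFormatError(f"missing attribute '{attr}'")
        energy = f["captured_energy"][...] if "captured_energy" in f else None
        return PSFDictionary(
            kernels=f["kernels"][...],
            zoom_levels=tuple(f.attrs["zoom_levels"]),
            wavelengths=tuple(f.attrs["wavelengths_um"]),
            sensor_shape=tuple(int(v) for v in f.attrs["sensor_shape"]),
            patch_size=int(f.attrs["patch_size"]),
            sampling_um=float(f.attrs["sampling_um"]),
            captured_energy=energy,
        )


def mtf(psf, sampling_um: float = SENSOR_PIXEL_UM,
        n_bins: int = None) -> tuple:
    """Radially averaged modulation transfer function of a PSF kernel.

    Returns (frequencies in cycles/mm, contrast).  The kernel must be
    normalized to unit sum so that MTF(0) = 1.
    """
    k = psf.kernel if isinstance(psf, PSFKernel) else np.asarray(psf, float)
    if abs(k.sum() - 1.0) > 1e-6:
        raise ValueError("mtf requires a unit-sum kernel")
    n = k.shape[0]
    otf = np.abs(np.fft.fftshift(np.fft.fft2(k)))
    fy = np.fft.fftshift(np.fft.fftfreq(n, d=sampling_um * 1e-3))  # cyc/mm
    fr = np.hypot(*np.meshgrid(fy, fy, indexing="ij"))
    if n_bins is None:
        n_bins = n // 2 + 1
    fmax = float(np.abs(fy).max())
    edges = np.linspace(0.0, fmax, n_bins + 1)
    # Put zero frequency alone in the first bin so MTF(0) is exact.
    idx = np.clip(np.digitize(fr.ravel(), edges[1:], right=False), 0, n_bins - 1)
    sums = np.bincount(idx, weights=otf.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    valid = counts > 0
    freqs = 0.5 * (edges[:-1] + edges[1:])
    freqs[0] = 0.0
    return freqs[valid], (sums[valid] / counts[valid])
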