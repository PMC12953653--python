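"""Parametric Zernike pupil model and PSF rendering.

The zoom objective's point spread function varies with magnification, field
position and wavelength.  This module renders those PSFs from a parametric
pupil-function model: a circular aperture carrying a Zernike phase whose
coefficients grow with normalized field radius and with a per-magnification
severity factor (defocus and astigmatism ~ r^2, coma ~ r, spherical constant
across the field), plus a per-wavelength chromatic defocus offset.

Sampling is tied to the camera: the intensity PSF is the squared modulus of
the pupil's Fourier transform, and the pupil disk radius (in frequency
samples) is chosen so that the transform's spatial sampling equals the sensor
pixel pitch (3.45 um).  The image-side NA is the object-side NA divided by the
magnification, so high magnifications produce broad, diffraction-dominated
kernels and low magnifications compact ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np

__all__ = [
    "PupilModel",
    "PSFKernel",
    "render_psf",
    "pupil_function",
    "grid_shape",
    "field_coordinates",
    "DEFAULT_WAVELENGTHS_UM",
    "CHANNEL_WAVELENGTH_UM",
    "DEFAULT_SENSOR_SHAPE",
    "DEFAULT_PATCH_SIZE",
    "SENSOR_PIXEL_UM",
]

#: F/d/C spectral lines used for the three color channels (um).
DEFAULT_WAVELENGTHS_UM = (0.486, 0.588, 0.656)

#: RGB channel -> wavelength (um): red=C line, green=d line, blue=F line.
CHANNEL_WAVELENGTH_UM = {0: 0.656, 1: 0.588, 2: 0.486}

DEFAULT_SENSOR_SHAPE = (1536, 2048)  # (height, width) px of the FLIR CMOS
DEFAULT_PATCH_SIZE = 256
SENSOR_PIXEL_UM = 3.45


def default_na_of_beta(beta: float) -> float:
    """Object-side NA schedule: NA grows with magnification, capped at 1.1.

    Chosen so the image-side NA (= NA/beta) stays as large as the aperture
    allows, keeping the camera-plane PSF as compact as the optics permit.
    """
    return min(1.1, 0.0225 * beta)


@dataclass(frozen=True)
class PupilModel:
    """Field-, magnification- and wavelength-dependent Zernike pupil.

    Coefficient amplitudes are in waves at the field edge (r = 1) and at
    maximum severity; they scale with normalized field radius as documented
    per term and with ``severity(beta)``, which ramps from ``severity_floor``
    to 1 across ``beta_range`` (log scale).
    """

    na_of_beta: callable = default_na_of_beta
    defocus_w: float = 0.25       # Z4, ~ r^2
    astig_w: float = 0.20         # Z5/Z6, ~ r^2, oriented by field azimuth
    coma_w: float = 0.15          # Z7/Z8, ~ r, oriented by field azimuth
    spherical_w: float = 0.10     # Z11, field-constant
    chromatic_defocus: dict = field(
        default_factory=lambda: {0.486: 0.15, 0.588: 0.0, 0.656: -0.12}
    )
    wavelengths: tuple = DEFAULT_WAVELENGTHS_UM
    beta_range: tuple = (10.0, 100.0)
    severity_floor: float = 0.4

    def severity(self, beta: float) -> float:
        b0, b1 = self.beta_range
        t = math.log(max(beta, 1e-12) / b0) / math.log(b1 / b0)
        t = min(1.0, max(0.0, t))
        return self.severity_floor + (1.0 - self.severity_floor) * t

    def coefficients(self, beta: float, r: float, phi: float,
                     wavelength_um: float) -> dict:
        """Zernike coefficients (waves, Noll indexing) for one field point."""
        s = self.severity(beta)
        chrom = self.chromatic_defocus.get(round(wavelength_um, 3), 0.0)
        return {
            4: self.defocus_w * r**2 * s + chrom,
            5: self.astig_w * r**2 * s * math.sin(2 * phi),
            6: self.astig_w * r**2 * s * math.cos(2 * phi),
            7: self.coma_w * r * s * math.sin(phi),
            8: self.coma_w * r * s * math.cos(phi),
            11: self.spherical_w * s,
        }


@dataclass
class PSFKernel:
    """A normalized blur kernel with its 4D index metadata."""

    kernel: np.ndarray
    beta: float
    field_rc: tuple
    wavelength_um: float
    captured_energy: float = 1.0

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kernel must be square 2D")
        if k.shape[0] % 2 != 1:
            raise ValueError("kernel side must be odd")
        if np.any(k < 0):
            raise ValueError("kernel entries must be non-negative")
        if abs(k.sum() - 1.0) > 1e-6:
            raise ValueError("kernel must sum to 1 within 1e-6")
        self.kernel = k

    @property
    def side(self) -> int:
        return self.kernel.shape[0]


def grid_shape(sensor_shape: tuple = DEFAULT_SENSOR_SHAPE,
               patch_size: int = DEFAULT_PATCH_SIZE) -> tuple:
    """Field-grid shape (rows, cols) tiling the sensor into patches.

    With the 2048x1536 sensor and 256 px patches this is (6, 8): 48 field
    cells per zoom state.
    """
    if patch_size <= 0:
        raise ValueError("patch_size must be positive")
    h, w = sensor_shape
    if h % patch_size or w % patch_size:
        warnings.warn(
            f"patch_size {patch_size} does not divide sensor {sensor_shape}; "
            "using floor division", stacklevel=2)
    return (h // patch_size, w // patch_size)


def field_coordinates(field_rc: tuple, grid: tuple,
                      sensor_shape: tuple = DEFAULT_SENSOR_SHAPE) -> tuple:
    """Normalized field radius r in [0,1] and azimuth of a grid cell center."""
    rows, cols = grid
    row, col = field_rc
    if not (0 <= row < rows and 0 <= col < cols):
        raise IndexError(f"field cell {field_rc} outside grid {grid}")
    h, w = sensor_shape
    cy = (row + 0.5) * (h / rows) - h / 2.0
    cx = (col + 0.5) * (w / cols) - w / 2.0
    rmax = math.hypot(h / 2.0, w / 2.0)
    return math.hypot(cx, cy) / rmax, math.atan2(cy, cx)


# Zernike polynomials, Noll indexing, unit RMS normalization.
def _zernike(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    if j == 4:
        return math.sqrt(3.0) * (2 * rho**2 - 1)
    if j == 5:
        return math.sqrt(6.0) * rho**2 * np.sin(2 * theta)
    if j == 6:
        return math.sqrt(6.0) * rho**2 * np.cos(2 * theta)
    if j == 7:
        return math.sqrt(8.0) * (3 * rho**3 - 2 * rho) * np.sin(theta)
    if j == 8:
        return math.sqrt(8.0) * (3 * rho**3 - 2 * rho) * np.cos(theta)
    if j == 11:
        return math.sqrt(5.0) * (6 * rho**4 - 6 * rho**2 + 1)
    raise ValueError(f"unsupported Zernike index {j}")


def pupil_disk_radius(pupil: PupilModel, beta: float, wavelength_um: float,
                      pad: int = 512,
                      pixel_um: float = SENSOR_PIXEL_UM) -> float:
    """Pupil disk radius in frequency samples for pitch-matched sampling.

    radius = NA_img / lambda * pad * pixel, with NA_img = NA(beta) / beta.
    """
    na = pupil.na_of_beta(beta)
    if not 0.0 < na <= 1.1:
        raise ValueError(f"NA {na:g} outside (0, 1.1]")
    na_img = na / beta
    return na_img / (wavelength_um * 1e-6) * pad * (pixel_um * 1e-6)


def pupil_function(pupil: PupilModel, beta: float, field_rc: tuple,
                   wavelength_um: float, *, grid: tuple = None,
                   pad: int = 512, disk_radius: float = None,
                   sensor_shape: tuple = DEFAULT_SENSOR_SHAPE) -> np.ndarray:
    """Complex pupil function sampled on a pad x pad frequency grid.

    The aperture is a centered disk of ``disk_radius`` samples (computed from
    the NA schedule when not given) carrying the Zernike phase for the given
    field cell, magnification and wavelength.
    """
    if grid is None:
        grid = grid_shape(sensor_shape)
    r, phi = field_coordinates(field_rc, grid, sensor_shape)
    if disk_radius is None:
        disk_radius = pupil_disk_radius(pupil, beta, wavelength_um, pad)
    if disk_radius >= pad / 2:
        raise ValueError("pupil disk exceeds the frequency grid; increase pad")

    coords = np.arange(pad) - pad // 2
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rho = np.hypot(xx, yy) / disk_radius
    mask = rho <= 1.0
    theta = np.arctan2(yy, xx)

    phase = np.zeros((pad, pad))
    coeffs = pupil.coefficients(beta, r, phi, wavelength_um)
    rho_m = rho[mask]
    theta_m = theta[mask]
    acc = np.zeros(rho_m.shape)
    for j, c in coeffs.items():
        if c != 0.0:
            acc += c * _zernike(j, rho_m, theta_m)
    phase[mask] = 2.0 * math.pi * acc

    p = np.zeros((pad, pad), dtype=complex)
    p[mask] = np.exp(1j * phase[mask])
    return p


def render_psf(pupil: PupilModel, beta: float, field_rc: tuple,
               wavelength_um: float, *, grid: tuple = None, pad: int = 512,
               kernel_size: int = 33, min_energy: float = 0.5,
               disk_radius: float = None,
               sensor_shape: tuple = DEFAULT_SENSOR_SHAPE) -> PSFKernel:
    """Render one PSF kernel: |FFT(pupil)|^2, center-cropped and unit-normalized.

    ``captured_energy`` on the returned kernel records the fraction of the
    full-grid PSF energy inside the crop before normalization; a value below
    ``min_energy`` raises, flagging a kernel too broad for the support.
    """
    if wavelength_um not in pupil.wavelengths:
        raise ValueError(
            f"wavelength {wavelength_um} not in pupil model {pupil.wavelengths}")
    if kernel_size % 2 != 1 or kernel_size < 3:
        raise ValueError("kernel_size must be odd and >= 3")
    p = pupil_function(pupil, beta, field_rc, wavelength_um, grid=grid,
                       pad=pad, disk_radius=disk_radius,
                       sensor_shape=sensor_shape)
    psf = np.abs(np.fft.fftshift(np.fft.fft2(p))) ** 2
    c = pad // 2
    h = kernel_size // 2
    crop = psf[c - h:c + h + 1, c - h:c + h + 1]
    total = psf.sum()
    captured = float(crop.sum() / total)
    if captured < min_energy:
        raise ValueError(
            f"kernel captures only {captured:.3f} of the PSF energy "
            f"(min {min_energy}); enlarge kernel_size")
    kernel = crop / crop.sum()
    return PSFKernel(kernel=kernel, beta=beta, field_rc=tuple(field_rc),
                     wavelength_um=wavelength_um, captured_energy=captured)
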