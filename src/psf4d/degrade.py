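"""Paired-sample degradation pipeline: GT -> blur -> noise -> downsample.

The dataset recipe follows the image-formation chain of the zoom microscope:
ground-truth images are partitioned into the dictionary's field tiles, each
tile convolved by its looked-up spatially-variant PSF (per color channel,
with its chromatic wavelength), Gaussian read noise of standard deviation
sigma in [2, 10] on the 8-bit scale is added, and the result is downsampled
by 2 with area averaging — yielding degraded inputs at half the GT side.

The GT frame is mapped onto the centered 2x2 block of the sensor's field
grid (a configurable field window), so a 512x512 GT sees four distinct
per-channel kernels, matching the patch-wise training pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dictionary import PSFDictionary, rgb_wavelength_index
from .forward_ops import chw_to_hwc, downsample2x, hwc_to_chw, patch_convolve
from .specimens import SpecimenImage, generate_specimen

__all__ = [
    "DegradedSample", "field_window_cells", "psf_set_for", "degrade",
    "augment", "build_dataset", "DatasetManifest",
]

SIGMA_RANGE = (2.0, 10.0)


@dataclass
class DegradedSample:
    """A paired training sample.

    ``input_y`` is (h, w, 3), ``gt_x`` is (2h, 2w, 3), both float in [0, 1];
    ``psf_set`` is (tile_rows, tile_cols, 3, k, k) with channel order RGB;
    ``sigma`` is the noise std on the 8-bit scale; ``tile``/``margin`` are
    the patch-convolution parameters needed to re-apply the forward model.
    """

    input_y: np.ndarray
    gt_x: np.ndarray
    psf_set: np.ndarray
    sigma: float
    beta: float
    seed: int
    tile: int
    margin: int
    style: str = ""

    def __post_init__(self) -> None:
        if self.gt_x.shape[0] != 2 * self.input_y.shape[0]:
            raise ValueError("GT side must be twice the input side")
        if self.sigma != 0.0 and not SIGMA_RANGE[0] <= self.sigma <= SIGMA_RANGE[1]:
            raise ValueError(f"sigma {self.sigma} outside {SIGMA_RANGE}")
        gr, gc = self.psf_set.shape[:2]
        h = self.gt_x.shape[0]
        if gr * self.tile != h or gc * self.tile != self.gt_x.shape[1]:
            raise ValueError("psf_set grid does not tile the GT image")


def field_window_cells(dictionary: PSFDictionary, window: tuple = (2, 2)):
    """Centered block of field cells a GT frame maps onto (rows, cols lists)."""
    rows, cols = dictionary.grid
    wr, wc = window
    if wr > rows or wc > cols:
        raise ValueError(f"field window {window} exceeds grid {(rows, cols)}")
    r0 = (rows - wr) // 2
    c0 = (cols - wc) // 2
    return list(range(r0, r0 + wr)), list(range(c0, c0 + wc))


def psf_set_for(dictionary: PSFDictionary, beta: float,
                window: tuple = (2, 2)) -> np.ndarray:
    """Per-tile, per-RGB-channel kernels for a GT frame at magnification beta."""
    rws, cls = field_window_cells(dictionary, window)
    k = dictionary.kernel_size
    out = np.empty((len(rws), len(cls), 3, k, k))
    for i, r in enumerate(rws):
        for j, c in enumerate(cls):
            for ch in range(3):
                wi = rgb_wavelength_index(ch, dictionary.wavelengths)
                out[i, j, ch] = dictionary.cell_kernel(beta, (r, c), wi)
    return out


def degrade(gt, dictionary: PSFDictionary = None, beta: float = 60.0,
            sigma: float = 6.0, seed: int = 0, psf_set: np.ndarray = None,
            margin: int = 32, clip: bool = True) -> DegradedSample:
    """Degrade a ground-truth image through the spatially-variant PSF model.

    Order of operations: per-channel patch convolution, additive Gaussian
    noise with std ``sigma`` on the 0-255 scale, then 2x area downsampling.
    The kernels come from ``psf_set`` if given, else are looked up in
    ``dictionary`` for the centered 2x2 field window.  ``sigma = 0`` is
    accepted as a noiseless diagnostic mode; training data uses [2, 10].
    """
    if sigma != 0.0 and not SIGMA_RANGE[0] <= sigma <= SIGMA_RANGE[1]:
        raise ValueError(f"sigma must be 0 or lie in {SIGMA_RANGE}, got {sigma}")
    if isinstance(gt, SpecimenImage):
        pixels, style = gt.pixels, gt.style
    else:
        pixels, style = np.asarray(gt, dtype=float), ""
    h, w = pixels.shape[:2]
    if psf_set is None:
        if dictionary is None:
            raise ValueError("either a dictionary or an explicit psf_set is required")
        psf_set = psf_set_for(dictionary, beta)
    gr, gc = psf_set.shape[:2]
    if h % gr or w % gc or (h // gr) != (w // gc):
        raise ValueError("GT shape incompatible with psf_set tiling")
    tile = h // gr
    margin = int(min(margin, tile // 2))

    x = hwc_to_chw(pixels)
    blurred = patch_convolve(x, psf_set, tile=tile, margin=margin).data
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = blurred + (sigma / 255.0) * rng.standard_normal(blurred.shape)
    else:
        noisy = blurred
    y = downsample2x(noisy).data
    if clip:
        y = np.clip(y, 0.0, 1.0)
    return DegradedSample(
        input_y=chw_to_hwc(y), gt_x=pixels, psf_set=psf_set, sigma=float(sigma),
        beta=float(beta), seed=int(seed), tile=tile, margin=margin, style=style)


def _dihedral(arr: np.ndarray, t: int, axes=(0, 1)) -> np.ndarray:
    """Apply the t-th (0-7) dihedral transform over the given axes."""
    out = np.rot90(arr, k=t % 4, axes=axes)
    if t >= 4:
        out = np.flip(out, axis=axes[1])
    return np.ascontiguousarray(out)


def augment(sample: DegradedSample) -> list:
    """The 8 dihedral variants of a paired sample.

    The transform is applied consistently to the input, the GT and the PSF
    set — both the tile grid layout and each kernel's support — so the
    degradation relation between input and GT is preserved.
    """
    out = []
    for t in range(8):
        psf = _dihedral(sample.psf_set, t, axes=(0, 1))
        psf = _dihedral(psf, t, axes=(3, 4))
        out.append(replace(
            sample,
            input_y=_dihedral(sample.input_y, t),
            gt_x=_dihedral(sample.gt_x, t),
            psf_set=np.ascontiguousarray(psf),
        ))
    return out


@dataclass
class DatasetManifest:
    root: Path
    table: pd.DataFrame

    @property
    def csv_path(self) -> Path:
        return self.root / "manifest.csv"

    def content_hash(self) -> str:
        return hashlib.sha256(
            self.table.to_csv(index=False).encode()).hexdigest()


def _save_png(path: Path, img: np.ndarray) -> None:
    arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def build_dataset(out_dir, dictionary: PSFDictionary, n_gt: int,
                  zoom_levels=None, gt_size: int = 512, seed: int = 0,
                  styles=("texture", "cells", "grating", "usaf"),
                  margin: int = 32, with_augment: bool = True) -> DatasetManifest:
    """Generate a paired dataset on disk with a manifest CSV.

    For every GT phantom and zoom level, one degraded pair is produced with
    sigma drawn uniformly from [2, 10]; dihedral augmentation expands each
    pair eightfold.  Fully deterministic from the master seed.
    """
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    if zoom_levels is None:
        zoom_levels = dictionary.zoom_levels
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    idx = 0
    for i in range(n_gt):
        style = styles[i % len(styles)]
        gt_seed = int(master.integers(0, 2**31 - 1))
        gt = generate_specimen(gt_seed, size=gt_size, style=style)
        for beta in zoom_levels:
            sigma = float(master.uniform(*SIGMA_RANGE))
            noise_seed = int(master.integers(0, 2**31 - 1))
            base = degrade(gt, dictionary, beta=beta, sigma=sigma,
                           seed=noise_seed, margin=margin)
            variants = augment(base) if with_augment else [base]
            for t, s in enumerate(variants):
                name = f"sample_{idx:06d}"
                _save_png(root / f"{name}_input.png", s.input_y)
                _save_png(root / f"{name}_gt.png", s.gt_x)
                rows.append(dict(
                    path=name, beta=float(beta), sigma=sigma,
                    seed=noise_seed, gt_seed=gt_seed, style=style,
                    transform=t, tile=s.tile, margin=s.margin))
                idx += 1
    table = pd.DataFrame(rows)
    manifest = DatasetManifest(root=root, table=table)
    table.to_csv(manifest.csv_path, index=False)
    return manifest
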