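# psf4d

Simulation and physics-guided restoration for a liquid-lens continuous-zoom
microscope with spatially-variant, chromatic, magnification-dependent blur.

Continuous-zoom microscopes built on electrowetting liquid lenses trade
aberration control for zoom range: as the applied voltage reshapes the
liquid interface, the point spread function (PSF) changes with the
magnification, with the position in the field of view, and with wavelength.
`psf4d` models that degradation end to end and inverts it:

1. **Optics** — the Young–Lippmann focusing law of the liquid lens,
   `f(U) = -D(n_c - n_n) / [cos(theta_0) + eps*eps_0*U^2/(2*H*gamma)]`, and the
   two-group zoom magnification
   `beta = (1 - Phi_f u)^-1 [1 + Phi_c(Phi_f + 1/u)^-1 - Phi_f d]^-1`,
   plus solvers that lay out the group powers along a 10x–100x trajectory.
2. **4D PSF dictionary** — a Zernike pupil model renders normalized blur
   kernels indexed by (zoom level, field row, field col, wavelength): 48
   field cells (8x6) per zoom state for a 2048x1536 sensor at 256 px
   patches, three wavelengths (0.486/0.588/0.656 um), stored in HDF5.
3. **Forward model** — procedural phantom specimens degraded by patch-wise
   PSF convolution, Gaussian noise (sigma 2–10 on the 8-bit scale) and 2x
   area downsampling, yielding paired 256x256 inputs / 512x512 ground truth.
4. **Restoration** — a content-adaptive learnable Wiener filter
   (`x_hat = F^H[conj(D_K) F y / (|D_K|^2 + e^{alpha_c} sum_d |D_{G_d}|^2)]`,
   per color channel, with learnable strengths, predicted regularization
   kernels and a bounded PSF-spectrum correction) feeding a
   degradation-guided transformer (frequency-domain PSF/feature fusion and
   channel attention whose keys are modulated by degradation features) with
   a 2x sub-pixel upsampler.
5. **Training** — a physics-constrained composite loss (GT fidelity +
   re-degradation consistency + MS-SSIM + total variation) optimized with
   Adam and cosine warm restarts, all on the package's own numpy autograd
   engine; no GPU or deep-learning framework required.

It is aimed at computational-imaging researchers who want a self-contained,
inspectable model of spatially-variant deconvolution with exactly known
kernels — every operator has a dense or brute-force oracle in the test
suite.

## Worked example

```python
from psf4d import build_dictionary, generate_specimen, degrade, psnr, ssim
from psf4d.dgnet import DegradationGuidedRestorer, NetworkConfig
from psf4d.training import bicubic_upsample

# 4D PSF dictionary on a desk-scale field grid (2x2 cells, six zoom levels)
d = build_dictionary(sensor_shape=(512, 512), patch_size=256,
                     zoom_levels=(10., 20., 40., 60., 80., 100.), pad=256)

gt = generate_specimen(seed=11, size=128, style="cells")   # phantom specimen
sample = degrade(gt, d, beta=60.0, sigma=6.0, seed=3)       # blur+noise+2x down

model = DegradationGuidedRestorer(NetworkConfig("tiny"), seed=0)
restored = model.restore(sample.input_y, sample.psf_set)    # 64x64 -> 128x128

print(psnr(bicubic_upsample(sample.input_y), gt.pixels))
print(psnr(restored, gt.pixels))
```

prints

```
input  vs GT : PSNR 15.05 dB, SSIM 0.294  (bicubic 2x)
output vs GT : PSNR 16.49 dB, SSIM 0.404  (Wiener + DGT, untrained)
```

— the +1.4 dB here comes purely from the Wiener front end with the true
kernels; training the model (see `psf4d.training.train`) adds the learned
residual and widens the margin.  A 5-epoch tiny-profile run on 64 synthetic
pairs reaches ~1.7 dB over bicubic on held-out samples.

The CLI wraps the same library:

```bash
psf4d zoomtable --beta-min 10 --beta-max 100 --levels 6 --out zoom.csv
psf4d build-dict --levels 10,60,100 --out dict.h5
psf4d simulate --dict dict.h5 --n 20 --out data/ --seed 7
psf4d train --config train.yaml --dict dict.h5 --data data/ --out model.npz
psf4d eval --ckpt model.npz --dict dict.h5 --data val/ --out metrics.csv
psf4d restore --input img.png --dict dict.h5 --beta 60 --out restored.png
```

`zoomtable` solves the group powers along the zoom trajectory, e.g.

```
beta,phi_front,phi_rear
10.000000000000004,7.147479210770191,6.4628721871492845
15.848931924611131,7.30965003528282,3.8262465298812973
...
99.99999999999977,7.958333333333333,0.2941550925925986
```

— all powers within the −5..+10 diopter range of the liquid-lens hardware.

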