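# Methods

This note documents the models, numerical choices and limitations behind
`psf4d`: a desk-scale simulation and restoration pipeline for a liquid-lens
continuous-zoom microscope with spatially-variant, chromatic,
magnification-dependent blur.

## First-order optics

The electrowetting liquid lens follows the Young–Lippmann focusing law

    f(U) = -D (n_c - n_n) / [ cos(theta_0) + eps*eps_0*U^2 / (2*H*gamma) ],

so the optical power 1/f is affine in U^2 — the property the package's
regression invariant checks.  The two-group zoom objective with fixed
object/image conjugates has overall magnification

    beta = (1 - Phi_f*u)^-1 * [ 1 + Phi_c (Phi_f + 1/u)^-1 - Phi_f*d ]^-1,

with front/rear group powers `Phi_f`, `Phi_c` (diopters), working distance
`u` and group separation `d` (meters, both constant during zooming; the
relay-plane offset is carried as metadata only).

Inverting beta for the two powers is under-determined, so the package fixes
a front-power schedule — linear in log(beta) between endpoint values chosen
so the front group carries roughly sqrt(beta) of the total magnification
(`Phi_f = (1 - 0.45/sqrt(beta))/u` at the range endpoints) — and solves the
rear power by bracketed root finding (Brent), rejecting brackets that
straddle the hyperbolic pole of the rear factor.  With the default template
(`u = 0.12 m`, `d = 0.1 m`) the whole 10x–100x range is reachable with both
group powers inside the −5 to +10 diopter interval of the liquid-lens
hardware.  The solved configuration round-trips through the forward formula
to 1e-6 relative tolerance (in practice ~1e-15).  The schedule and template
are stand-ins: the real instrument's power split along the zoom trajectory
is set by its lens prescription, which is not modeled here.

## PSF simulation

Ray tracing is replaced by a parametric Zernike pupil model.  For one
(magnification, field cell, wavelength) combination, a circular aperture
carries the phase `2*pi * sum_j c_j Z_j(rho, theta)` with Noll-indexed,
RMS-normalized polynomials and coefficients (in waves)

| term | field scaling | default amplitude |
|---|---|---|
| defocus Z4 | r^2 | 0.25 |
| astigmatism Z5/Z6 | r^2, oriented by field azimuth | 0.20 |
| coma Z7/Z8 | r, oriented by field azimuth | 0.15 |
| spherical Z11 | constant | 0.10 |
| chromatic defocus | constant per wavelength | +0.15 (486 nm), 0 (588), −0.12 (656) |

all multiplied by a severity factor ramping from 0.4 to 1.0 in log(beta)
across 10x–100x, emulating aberrations that worsen with magnification.  The
amplitudes were chosen once as a moderate (sub-wave, Strehl-regime)
aberration budget typical of a stitched zoom design and are config-exposed.

The intensity PSF is |FFT(pupil)|^2.  Sampling is pinned to the camera: with
image-side numerical aperture `NA_img = NA(beta)/beta` and 3.45 um pixels,
the pupil disk radius on the `pad = 512` frequency grid is
`NA_img/lambda * pad * 3.45 um`, which makes the transform's pixel pitch
exactly the sensor pitch at every magnification and wavelength.  The NA
schedule `NA(beta) = min(1.1, 0.0225*beta)` keeps the image-side cone as
fast as an NA <= 1.1 objective allows.  Kernels are center-cropped to 33x33
and renormalized to unit sum.  Because the image-side Airy envelope at high
magnification spans ~10 px and its encircled energy converges like 1/r, a
33 px crop cannot capture ~99.9% of the energy there; the captured fraction
(0.54–0.95 across the default range) is recorded in kernel metadata and an
assertion floor of 0.5 guards against pathologically broad kernels.
Renormalization preserves the unit-sum contract the Wiener filter and the
energy-conservation tests rely on.

The 4D dictionary stores kernels indexed by (zoom level, field row, field
col, wavelength) — 8x6 = 48 field cells per zoom state for the 2048x1536
sensor at 256 px patches, three wavelengths (0.486, 0.588, 0.656 um mapped
to B/G/R), six default zoom levels — in a single 6-D HDF5 dataset with the
geometry as attributes.  Lookup maps a pixel to its half-open tile and a
magnification to the nearest stored level (ties to the lower level); kernels
are never interpolated, since interpolation is not energy-preserving —
continuous-beta users re-render through the pupil model.

## Forward model (synthetic data)

Ground-truth phantoms are procedural (band-limited colored-noise texture,
Poisson-disk cell fields with membranes and nuclei, sinusoidal gratings,
USAF-1951-style bar triplets with the 2^(1/6) element progression), RGB in
[0, 1], deterministic per seed.  A GT frame maps onto the centered 2x2 block
of the sensor's field grid, so it sees four distinct per-channel kernels.

Degradation follows blur -> noise -> downsample:

1. **Patch convolution.** Each GT tile is convolved with its cell's kernel
   on an extended support of `margin + kernel_half` true neighboring pixels
   (mirrored only at the image boundary), and tiles are blended with linear
   ramps over `2*margin` px (default margin 32 at 512 GT, 16 at desk scale)
   whose weights sum to one.  With a uniform kernel this equals exact
   whole-image convolution away from the boundary (verified to machine
   precision); the ramps exist only to hide kernel *differences* at seams.
2. **Noise.** Additive Gaussian noise with sigma in [2, 10] on the 8-bit
   scale, added at GT resolution (sigma = 0 is a noiseless diagnostic mode).
3. **Downsampling.** 2x2 area averaging (the natural sensor-binning model),
   which halves the noise std — hence the (sigma/2/255)^2 noise-floor
   identity the physics loss is tested against.  Output clipped to [0, 1].

Dihedral augmentation (8 transforms) rotates/flips input, GT, the tile grid
*and* each kernel's support together, which preserves the physics residual
exactly.  Dataset generation is deterministic from one master seed and
writes 8-bit PNG pairs plus a manifest CSV (path, beta, sigma, seeds, style,
transform, tile, margin).

## Restoration model

**Tensor backend.** The learnable components run on a compact reverse-mode
autodiff engine written on numpy (`autograd.py`): elementwise ops, batched
matmul, FFT/IFFT with exact adjoints (complex values travel as stacked
real/imag planes), valid-mode convolution differentiable in image and
kernel, reflective padding via gather/scatter, and factor-2 bilinear
upsampling with an explicit transpose.  Every primitive is finite-difference
checked in the test suite.  float64 throughout: desk-scale problem sizes
make the 2x memory cost irrelevant and keep oracle comparisons tight.

**CALW (content-adaptive learnable Wiener).**  Per channel c:

    x_hat_c = F^H [ conj(D_K) F y_c / ( |D_K|^2 + e^{alpha_c} sum_d |D_{G_d}|^2 ) ]

with per-channel log-strengths `alpha_c` (initialized to log 1e-3, a weak
prior), D = 8 regularization kernels (fixed base bank: first derivatives,
Laplacian, four oriented second derivatives, identity-minus-mean — all
zero-sum — plus a zero-initialized content-predicted residual from a shallow
encoder on the RGB input), and a PSF spectrum correction
`corrected = otf * (1 + 0.5*tanh(g))` with a zero-initialized head, so the
correction is the exact identity at initialization and the DC magnitude
stays in [0.5, 1.5] by construction.  The correction is applied on the
kernel's own 33x33 spectrum and mapped back to a spatial kernel so that the
*same* corrected kernel drives both the Wiener filter and the physics loss.
Two grid adaptations connect the filter to the data: dictionary kernels live
on the GT grid, so they are 2x2 sum-binned to the input grid before the OTF
is built; and a degraded sample spans a 2x2 field window, so the filter uses
the window average of the corrected channel kernels (the physics loss keeps
the exact per-tile kernels).  The filter runs on a 16 px mirrored-padded
grid with circular convolution algebra, center-cropped afterwards to
suppress wrap-around ringing.  Correctness is anchored to a dense oracle:
the output equals solving the circulant normal equations
`(K^T K + e^alpha sum G^T G) x = K^T y` to < 1e-5 (in practice ~1e-15).

**Degradation-guided head.**  Features are conditioned on the blur in two
ways.  PDFF transforms feature maps to the frequency domain, modulates them
by the DC-normalized MTF of the sample's (binned, window-averaged) kernel
resampled to the feature scale, transforms back, and mixes with the
originals through a pointwise layer — a delta PSF leaves the modulated
branch exactly invariant.  DGMSA is channel-transposed multi-head attention
(Q/K/V are per-channel descriptors over space, L2-normalized, with a
learnable per-head temperature), chosen over spatial-window attention to
keep cost linear in pixel count; the degradation features are pooled and
mapped by a zero-initialized projection to a per-channel scale and bias on
the keys, `K' = K (1+s) + b`, so at initialization the operator equals plain
channel attention (verified against an explicit per-head loop oracle).  DGT
blocks stack pre-norm DGMSA and a gated (gelu) pointwise feed-forward with
residuals, in a 3-scale encoder-decoder (scales 1, 1/2, 1/4; skip
connections; pixel-unshuffle down, bilinear+pointwise up).  The output path
is a zero-initialized 3x3 head into a sub-pixel (pixel-shuffle) 2x
upsampler, added to the bilinearly upsampled Wiener output: at
initialization the model *is* the Wiener restoration, and training learns a
residual.  Profiles: `tiny` (channels 16/32/64, ~111k parameters,
CPU-trainable) and `base` (48/96/192).

## Loss and training

    L = w_fid * MSE(x_hat, gt)
      + w_phys * MSE( Down2(PatchConv(x_hat, corrected_psf_set)), y )
      + w_ssim * (1 - MS-SSIM(x_hat, gt))
      + w_tv * TV(x_hat)

The physics term re-degrades the restoration through the *identical*
operators used to create the data, so a perfect restoration of a noiseless
sample scores exactly zero and a noisy one sits on the (sigma/2/255)^2
noise floor.  The composite includes an explicit GT-fidelity MSE because
structural similarity alone under-constrains color fidelity.  Default
weights (1, 0.5, 0.15, 1e-4) put the terms at comparable magnitudes on the
synthetic fixtures; all are config-exposed.  MS-SSIM uses the standard
11x11 Gaussian window, dyadic scales and exponents (0.0448, 0.2856, 0.3001,
0.2363, 0.1333), renormalized when fewer than five levels fit the image;
TV is mean anisotropic |dx| + |dy|.

Training is Adam (moments 0.9/0.999), initial learning rate 2e-5, batch
size 8, cosine annealing restarting every 20 epochs — the recipe of the
imaging system this package models; only the epoch count is scaled down
(default 5) for desk-scale runs.  All randomness flows from one master
seed; checkpoints carry model and optimizer state, and a resumed run
reproduces an uninterrupted one to the last bit (tested).  Only phase-1
style training on simulated degradations is implemented; pairing against a
second instrument's captures is a dataset swap, not extra machinery.

## Problem sizes

Unit tests exercise the full 256->512 patch geometry and the full-sensor
864-kernel dictionary; training runs use 64x64 inputs / 128x128 GT with the
standard 33x33 kernels (tile = 64, margin 16), 64 training and 16 held-out
pairs, five epochs — sizes chosen so the whole pipeline (simulation,
training, evaluation) runs end to end on one CPU core in minutes.  At these
sizes the trained tiny model clears the bicubic-upsampling baseline by
about 1.7 dB PSNR, most of it contributed by the Wiener front end; the
attention head's margin grows with training budget.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the real problem — spatially
variant chromatic blur growing with field radius and magnification,
mid-level Gaussian read noise, 2x resolution loss — with exactly known
kernels.  It does not reproduce: kernel mismatch beyond the 1 px-shift
ablation (real PSFs differ from simulated ones by manufacturing tolerances),
non-Gaussian sensor noise (shot noise, fixed-pattern), ghosting and
low-contrast veiling from liquid-lens transmittance, defocus from axial
stage error, or natural specimen statistics.  Passing tests therefore
demonstrate correctness of the operators and trainability of the model
under the stated degradation model, not field performance of the
instrument; the headline capture-set figures of the real system depend on
its hardware and trained weights and are out of scope here.

## Numerical choices and edge cases

* Unit-sum kernel tolerance 1e-6; OTF DC magnitude accepted in [0.5, 1.5]
  (the correction bound); Wiener denominator must exceed 1e-300 or a
  singular-filter error is raised.
* Nearest-zoom-level ties resolve to the lower level; field tiles are
  half-open, 0-based, origin top-left.
* `solve_powers` samples 513 points across the power bounds to bracket the
  rear-power root and reports the achievable range when the target is
  infeasible.
* MS-SSIM contrast terms are clamped at zero (plus 1e-12) before the
  fractional power; images smaller than the window pyramid are rejected.
* PSNR of identical images reports a 100 dB cap instead of infinity.
* Degenerate inputs (odd image sides for downsampling, non-dividing tile
  sizes, heads not dividing channels, out-of-range sigma or NA) raise
  typed errors at the boundary rather than propagating NaNs; a non-finite
  training loss aborts with the last finite parameters.
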