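# Example configuration for `psf4d train` / `psf4d build-dict`.

pupil:
  defocus_w: 0.25        # waves at field edge, max severity
  astig_w: 0.20
  coma_w: 0.15
  spherical_w: 0.10
  severity_floor: 0.4
  chromatic_defocus:
    0.486: 0.15
    0.588: 0.0
    0.656: -0.12

network:
  profile: tiny          # tiny | base

loss:
  w_fid: 1.0
  w_phys: 0.5
  w_ssim: 0.15
  w_tv: 1.0e-4

train:
  batch_size: 8
  lr: 2.0e-5
  beta1: 0.9
  beta2: 0.999
  epochs: 5
  restart_period: 5      # cosine-annealing restart period (reference: 20)
  ssim_levels: 4
  seed: 7
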