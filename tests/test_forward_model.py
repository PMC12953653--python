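"""Phantom specimens and the blur -> noise -> downsample degradation recipe."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from psf4d.degrade import (augment, build_dataset, degrade,
                           field_window_cells)
from psf4d import specimens as sp
from psf4d.forward_ops import downsample2x, hwc_to_chw, patch_convolve


def gaussian_psf_set(sigma=2.5, grid=(2, 2), ksize=33):
    x = np.arange(ksize) - ksize // 2
    g = np.exp(-0.5 * np.add.outer(x**2, x**2) / sigma**2)
    g /= g.sum()
    return np.broadcast_to(g, grid + (3, ksize, ksize)).copy()


def delta_psf_set(grid=(2, 2), ksize=33):
    k = np.zeros((ksize, ksize))
    k[ksize // 2, ksize // 2] = 1.0
    return np.broadcast_to(k, grid + (3, ksize, ksize)).copy()


class TestSpecimens:
    @pytest.mark.parametrize("style", sp.STYLES)
    def test_deterministic_and_in_range(self, style):
        a = sp.generate_specimen(42, size=128, style=style)
        b = sp.generate_specimen(42, size=128, style=style)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.min() >= 0.0 and a.pixels.max() <= 1.0
        assert a.pixels.shape == (128, 128, 3)

    def test_different_seeds_differ(self):
        a = sp.generate_specimen(1, size=64, style="texture")
        b = sp.generate_specimen(2, size=64, style="texture")
        assert np.abs(a.pixels - b.pixels).max() > 1e-3

    def test_grating_fourier_peak_at_requested_frequency(self):
        freq = 11
        img = sp.generate_specimen(5, size=128, style="grating",
                                   freq=freq).pixels[..., 1]
        spec = np.abs(np.fft.fft2(img - img.mean()))
        ky, kx = np.unravel_index(np.argmax(spec), spec.shape)
        kx = min(kx, 128 - kx)
        assert (ky % 128, kx) in {(0, freq), (128 - freq, freq)} or kx == freq

    def test_usaf_widths_follow_sixth_root_of_two(self):
        ratios = [sp.usaf_bar_width(0, e) / sp.usaf_bar_width(0, e + 1)
                  for e in range(1, 6)]
        assert np.allclose(ratios, 2 ** (1 / 6), rtol=1e-12)
        assert sp.usaf_bar_width(1, 1) == pytest.approx(
            sp.usaf_bar_width(0, 1) / 2)

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError, match="unknown style"):
            sp.generate_specimen(0, style="noise")

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            sp.generate_specimen(0, size=127)


class TestDegrade:
    def test_delta_kernels_noiseless_reduce_to_area_averaging(self):
        gt = sp.generate_specimen(3, size=128, style="texture")
        s = degrade(gt, psf_set=delta_psf_set(), sigma=0.0, seed=0,
                       margin=16)
        expected = downsample2x(hwc_to_chw(gt.pixels)).data
        assert np.abs(hwc_to_chw(s.input_y) - expected).max() < 1e-6

    def test_uniform_kernel_matches_whole_image_convolution(self):
        """Patch pipeline vs a circular-free full-image convolution oracle."""
        gt = sp.generate_specimen(3, size=128, style="cells")
        psf = gaussian_psf_set()
        x = hwc_to_chw(gt.pixels)
        ours = patch_convolve(x, psf, tile=64, margin=16).data
        oracle = np.stack([fftconvolve(x[c], psf[0, 0, 0], mode="same")
                           for c in range(3)])
        interior = (slice(None), slice(20, 108), slice(20, 108))
        assert np.abs(ours - oracle)[interior].max() < 1e-3

    def test_seeded_runs_are_byte_identical(self):
        gt = sp.generate_specimen(4, size=128, style="texture")
        a = degrade(gt, psf_set=gaussian_psf_set(), sigma=6.0, seed=9)
        b = degrade(gt, psf_set=gaussian_psf_set(), sigma=6.0, seed=9)
        assert np.array_equal(a.input_y, b.input_y)

    def test_linearity_before_noise(self):
        gt = sp.generate_specimen(5, size=128, style="texture").pixels
        psf = gaussian_psf_set()
        full = degrade(0.5 * gt, psf_set=psf, sigma=0.0, seed=0, clip=False)
        half = degrade(gt, psf_set=psf, sigma=0.0, seed=0, clip=False)
        assert np.abs(full.input_y - 0.5 * half.input_y).max() < 1e-6

    def test_unit_sum_kernels_preserve_mean_intensity(self):
        gt = sp.generate_specimen(6, size=128, style="texture").pixels
        s = degrade(gt, psf_set=gaussian_psf_set(), sigma=0.0, seed=0,
                       clip=False)
        interior = s.input_y[8:-8, 8:-8]
        assert abs(interior.mean() - gt[16:-16, 16:-16].mean()) < 1e-3

    def test_noise_std_matches_sigma(self):
        """Empirical std of the added noise (8-bit scale) within 3 percent."""
        gt = sp.generate_specimen(7, size=256, style="texture")
        psf = gaussian_psf_set(grid=(2, 2))
        clean = degrade(gt, psf_set=psf, sigma=0.0, seed=0, clip=False)
        resids = []
        for sigma in (2.0, 6.0, 10.0):
            noisy = degrade(gt, psf_set=psf, sigma=sigma, seed=123,
                               clip=False)
            resid = (noisy.input_y - clean.input_y) * 255.0
            # 2x2 area averaging halves the std
            resids.append(resid.std() / (sigma / 2.0))
        assert np.abs(np.asarray(resids) - 1.0).max() < 0.03

    def test_sigma_out_of_range_rejected(self):
        gt = sp.generate_specimen(1, size=64, style="texture")
        with pytest.raises(ValueError, match="sigma"):
            degrade(gt, psf_set=gaussian_psf_set(ksize=17), sigma=1.0)
        with pytest.raises(ValueError, match="sigma"):
            degrade(gt, psf_set=gaussian_psf_set(ksize=17), sigma=11.0)

    def test_dictionary_lookup_path(self, small_dict):
        gt = sp.generate_specimen(2, size=128, style="texture")
        s = degrade(gt, small_dict, beta=20.0, sigma=4.0, seed=1, margin=16)
        assert s.psf_set.shape == (2, 2, 3, 33, 33)
        assert s.input_y.shape == (64, 64, 3)
        # red channel kernel is the 0.656 um entry of the center-window cell
        rows, cols = field_window_cells(small_dict)
        expected = small_dict.cell_kernel(20.0, (rows[0], cols[0]), 2)
        assert np.array_equal(s.psf_set[0, 0, 0], expected)


class TestAugment:
    def make_sample(self):
        gt = sp.generate_specimen(8, size=128, style="cells")
        return degrade(gt, psf_set=gaussian_psf_set(), sigma=6.0, seed=2,
                          clip=False)

    def test_identity_transform_is_first(self):
        s = self.make_sample()
        variants = augment(s)
        assert len(variants) == 8
        assert np.array_equal(variants[0].input_y, s.input_y)
        assert np.array_equal(variants[0].psf_set, s.psf_set)

    def test_horizontal_flip_is_an_involution(self):
        s = self.make_sample()
        flipped = augment(s)[4]
        back = augment(flipped)[4]
        assert np.array_equal(back.input_y, s.input_y)
        assert np.array_equal(back.gt_x, s.gt_x)

    def test_physics_residual_invariant_under_all_transforms(self):
        """||Down(gt (*) psf) - input|| is preserved by every dihedral map."""
        s = self.make_sample()

        def residual(v):
            blurred = patch_convolve(hwc_to_chw(v.gt_x), v.psf_set,
                                     tile=v.tile, margin=v.margin).data
            return float(np.linalg.norm(downsample2x(blurred).data
                                        - hwc_to_chw(v.input_y)))

        r0 = residual(s)
        for v in augment(s):
            assert residual(v) == pytest.approx(r0, abs=1e-6)


class TestBuildDataset:
    def test_counts_files_and_determinism(self, small_dict, tmp_path):
        m1 = build_dataset(tmp_path / "a", small_dict, n_gt=2,
                              zoom_levels=(20.0, 60.0), gt_size=128, seed=3,
                              margin=16)
        # n_gt x levels x 8 dihedral transforms
        assert len(m1.table) == 2 * 2 * 8
        pngs = list((tmp_path / "a").glob("*_input.png"))
        assert len(pngs) == len(m1.table)
        m2 = build_dataset(tmp_path / "b", small_dict, n_gt=2,
                              zoom_levels=(20.0, 60.0), gt_size=128, seed=3,
                              margin=16)
        assert m1.content_hash() == m2.content_hash()

    def test_manifest_reload_round_trip(self, small_dict, tmp_path):
        from psf4d.training import samples_from_manifest
        m = build_dataset(tmp_path / "c", small_dict, n_gt=1,
                             zoom_levels=(60.0,), gt_size=128, seed=5,
                             margin=16, with_augment=False)
        loaded = samples_from_manifest(m.csv_path, small_dict)
        assert len(loaded) == 1
        s = loaded[0]
        assert s.gt_x.shape == (128, 128, 3)
        # 8-bit quantization bounds the reload error
        assert s.input_y.min() >= 0.0 and s.input_y.max() <= 1.0
        assert s.psf_set.shape == (2, 2, 3, 33, 33)

    def test_empty_dataset_rejected(self, small_dict, tmp_path):
        with pytest.raises(ValueError):
            build_dataset(tmp_path / "d", small_dict, n_gt=0)
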