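"""Composite loss terms and image-fidelity metrics."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from psf4d import autograd as ag
from psf4d import losses
from psf4d.degrade import degrade
from psf4d.forward_ops import hwc_to_chw
from psf4d.metrics import psnr, ssim
from psf4d.specimens import generate_specimen
from psf4d.training import LossWeights


def gaussian_psf_set(sigma=2.0, ksize=33):
    x = np.arange(ksize) - ksize // 2
    g = np.exp(-0.5 * np.add.outer(x**2, x**2) / sigma**2)
    g /= g.sum()
    return np.broadcast_to(g, (2, 2, 3, ksize, ksize)).copy()


def mid_range_gt(seed, size=128):
    """Texture phantom squeezed into [0.2, 0.8] so clipping never triggers."""
    base = generate_specimen(seed, size=size, style="texture").pixels
    return 0.2 + 0.6 * base


class TestPhysicsLoss:
    def test_true_gt_on_noiseless_sample_is_exact(self):
        gt = mid_range_gt(1)
        psf = gaussian_psf_set()
        s = degrade(gt, psf_set=psf, sigma=0.0, seed=0, margin=16)
        loss = losses.physics_loss(hwc_to_chw(s.gt_x), psf,
                                   hwc_to_chw(s.input_y),
                                   tile=s.tile, margin=s.margin)
        assert loss.item() < 1e-8

    @pytest.mark.parametrize("sigma", [2.0, 6.0, 10.0])
    def test_noise_floor_identity(self, sigma):
        """With the true GT, the physics residual is exactly the downsampled
        noise: E[loss] = (sigma/2/255)^2 within 10 percent over seeds."""
        gt = mid_range_gt(2)
        psf = gaussian_psf_set()
        ratios = []
        for seed in range(10):
            s = degrade(gt, psf_set=psf, sigma=sigma, seed=seed, margin=16)
            loss = losses.physics_loss(hwc_to_chw(s.gt_x), psf,
                                       hwc_to_chw(s.input_y),
                                       tile=s.tile, margin=s.margin)
            ratios.append(loss.item() / (sigma / 2.0 / 255.0) ** 2)
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_zero_restoration_gives_mean_square_input(self):
        gt = mid_range_gt(3)
        psf = gaussian_psf_set()
        s = degrade(gt, psf_set=psf, sigma=4.0, seed=1, margin=16)
        y = hwc_to_chw(s.input_y)
        loss = losses.physics_loss(np.zeros((3, 128, 128)), psf, y,
                                   tile=s.tile, margin=s.margin)
        assert loss.item() == pytest.approx(float(np.mean(y**2)), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        psf = gaussian_psf_set()
        with pytest.raises(ValueError, match="tile"):
            losses.physics_loss(np.zeros((3, 128, 128)), psf,
                                np.zeros((3, 64, 64)), tile=32, margin=16)


class TestMsSsimAndTv:
    def test_self_similarity_is_one(self, rng):
        a = ag.Tensor(rng.random((3, 64, 64)))
        assert losses.ms_ssim(a, a, levels=2).item() == pytest.approx(1.0, abs=1e-9)

    def test_single_scale_matches_skimage(self, rng):
        a = rng.random((64, 64))
        b = np.clip(a + 0.1 * rng.standard_normal(a.shape), 0, 1)
        ours = losses.ms_ssim(a[None], b[None], levels=1).item()
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=1.0)
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_blur_reduces_similarity(self, rng):
        from scipy.ndimage import gaussian_filter
        a = rng.random((1, 64, 64))
        soft = gaussian_filter(a, sigma=(0, 2, 2))
        assert losses.ms_ssim(a, soft, levels=2).item() < 0.95

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            losses.ms_ssim(np.zeros((1, 32, 32)), np.zeros((1, 32, 32)),
                           levels=3)

    def test_tv_of_constant_is_zero(self):
        assert losses.tv(np.full((3, 16, 16), 0.7)).item() == 0.0

    def test_tv_of_unit_step_matches_hand_count(self):
        """4x4 image, step across one column: 4 unit x-diffs out of 12,
        zero y-diffs -> TV = 4/12 = 1/3."""
        img = np.zeros((4, 4))
        img[:, 2:] = 1.0
        assert losses.tv(img[None]).item() == pytest.approx(1.0 / 3.0)

    def test_tv_gradient_flows(self):
        t = ag.Tensor(np.arange(16.0).reshape(1, 4, 4), requires_grad=True)
        losses.tv(t).backward()
        assert t.grad is not None and np.any(t.grad != 0)


class TestTotalLoss:
    def setup_sample(self):
        gt = mid_range_gt(4, size=64)
        psf = gaussian_psf_set()
        s = degrade(gt, psf_set=psf, sigma=0.0, seed=0, margin=16)
        return s, psf

    def test_perfect_restoration_without_tv_is_zero(self):
        s, psf = self.setup_sample()
        w = LossWeights(w_fid=1.0, w_phys=0.5, w_ssim=0.15, w_tv=0.0)
        total, terms = losses.total_loss(
            hwc_to_chw(s.gt_x), hwc_to_chw(s.gt_x), hwc_to_chw(s.input_y),
            psf, w, tile=s.tile, margin=s.margin, ssim_levels=1)
        assert total.item() < 1e-8
        assert terms["fid"] == 0.0

    def test_one_hot_physics_weight_reduces_to_physics_loss(self, rng):
        s, psf = self.setup_sample()
        x_hat = np.clip(hwc_to_chw(s.gt_x) + 0.01 * rng.standard_normal((3, 64, 64)), 0, 1)
        w = LossWeights(w_fid=0.0, w_phys=1.0, w_ssim=0.0, w_tv=0.0)
        total, _ = losses.total_loss(x_hat, hwc_to_chw(s.gt_x),
                                     hwc_to_chw(s.input_y), psf, w,
                                     tile=s.tile, margin=s.margin)
        direct = losses.physics_loss(x_hat, psf, hwc_to_chw(s.input_y),
                                     tile=s.tile, margin=s.margin)
        assert total.item() == pytest.approx(direct.item(), rel=1e-12)

    def test_matches_independent_recomputation(self, rng):
        """All four terms vs a straight-line numpy reimplementation."""
        from scipy.signal import fftconvolve
        s, psf = self.setup_sample()
        gt = hwc_to_chw(s.gt_x)
        y = hwc_to_chw(s.input_y)
        x_hat = np.clip(gt + 0.05 * rng.standard_normal(gt.shape), 0, 1)
        w = LossWeights(w_fid=1.0, w_phys=1.0, w_ssim=1.0, w_tv=1.0)
        total, terms = losses.total_loss(x_hat, gt, y, psf, w, tile=s.tile,
                                         margin=s.margin, ssim_levels=1)
        # independent recomputation
        fid = np.mean((x_hat - gt) ** 2)
        blurred = np.stack([fftconvolve(
            np.pad(x_hat[c], s.margin + 16, mode="reflect"), psf[0, 0, 0],
            mode="same")[s.margin + 16:-(s.margin + 16),
                         s.margin + 16:-(s.margin + 16)] for c in range(3)])
        down = blurred.reshape(3, 32, 2, 32, 2).mean(axis=(2, 4))
        phys = np.mean((down - y) ** 2)
        ssim_term = 1.0 - np.mean([structural_similarity(
            x_hat[c], gt[c], gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0) for c in range(3)])
        tv_term = (np.abs(np.diff(x_hat, axis=2)).mean()
                   + np.abs(np.diff(x_hat, axis=1)).mean())
        expected = fid + phys + ssim_term + tv_term
        assert terms["fid"] == pytest.approx(fid, rel=1e-10)
        assert terms["phys"] == pytest.approx(phys, rel=1e-6)
        assert terms["ssim"] == pytest.approx(ssim_term, abs=1e-6)
        assert terms["tv"] == pytest.approx(tv_term, rel=1e-10)
        assert total.item() == pytest.approx(expected, rel=1e-5)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w_fid=-1.0)
        with pytest.raises(ValueError):
            LossWeights(w_fid=0.0, w_phys=0.0, w_ssim=0.0, w_tv=0.0)

    def test_terms_are_non_negative(self, rng):
        s, psf = self.setup_sample()
        x_hat = rng.random((3, 64, 64))
        total, terms = losses.total_loss(
            x_hat, hwc_to_chw(s.gt_x), hwc_to_chw(s.input_y), psf,
            LossWeights(), tile=s.tile, margin=s.margin, ssim_levels=1)
        assert total.item() >= 0.0
        assert all(v >= 0.0 for v in terms.values())


class TestMetrics:
    def test_uniform_16_level_offset_closed_form(self):
        """8-bit images differing by exactly 16: MSE=256,
        PSNR = 10*log10(255^2/256) = 24.05 dB."""
        a = np.full((32, 32), 100.0)
        b = a + 16.0
        value = psnr(a, b, max_val=255.0)
        assert value == pytest.approx(10 * np.log10(255.0**2 / 256.0), abs=1e-12)
        assert round(value, 2) == 24.05

    def test_identical_images_hit_the_cap(self, rng):
        a = rng.random((16, 16))
        assert psnr(a, a) == 100.0
        assert ssim(a.copy(), a.copy()) == pytest.approx(1.0)

    def test_metrics_are_symmetric(self, rng):
        a = rng.random((32, 32, 3))
        b = rng.random((32, 32, 3))
        assert psnr(a, b) == pytest.approx(psnr(b, a), abs=1e-10)
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))
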