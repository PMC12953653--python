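"""Learnable Wiener front end: closed form, adaptivity and differentiability."""

import numpy as np
import pytest

from psf4d import autograd as ag
from psf4d import calw
from psf4d.degrade import degrade
from psf4d.forward_ops import downsample2x, hwc_to_chw
from psf4d.metrics import psnr
from psf4d.specimens import generate_specimen


def centered_gaussian(ksize=9, sigma=1.5):
    x = np.arange(ksize) - ksize // 2
    g = np.exp(-0.5 * np.add.outer(x**2, x**2) / sigma**2)
    return g / g.sum()


def circulant_matrix(kernel, n):
    """Dense circular-convolution matrix of a centered kernel on an n x n grid."""
    k = kernel.shape[0]
    kh = k // 2
    mat = np.zeros((n * n, n * n))
    for i in range(n):
        for j in range(n):
            resp = np.zeros((n, n))
            for dy in range(-kh, kh + 1):
                for dx in range(-kh, kh + 1):
                    resp[(i + dy) % n, (j + dx) % n] += kernel[dy + kh, dx + kh]
            mat[:, i * n + j] = resp.ravel()
    return mat


class TestWienerDeconvolve:
    def test_delta_kernel_zero_bank_is_identity(self, rng):
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        ctx = calw.WienerContext.from_kernels(
            [delta], 8, reg_bank=np.zeros((1, 3, 3)), alpha=np.zeros(1))
        y = rng.random((8, 8))
        out = calw.wiener_deconvolve(y, ctx, 0).data
        assert np.abs(out - y).max() < 1e-12

    def test_zero_input_gives_zero_output(self):
        ctx = calw.WienerContext.from_kernels([centered_gaussian(5)], 8)
        out = calw.wiener_deconvolve(np.zeros((8, 8)), ctx, 0).data
        assert np.abs(out).max() < 1e-15

    @pytest.mark.parametrize("n", [8, 16])
    def test_matches_dense_circulant_normal_equations(self, n):
        """Frequency-domain filter vs solving (K'K + e^a G'G) x = K'y densely."""
        regs = calw.base_reg_bank()[:2]
        worst = 0.0
        for seed in range(20):
            r = np.random.default_rng(seed)
            kern = centered_gaussian(5, 1.0) + 0.05 * r.random((5, 5))
            kern /= kern.sum()
            alpha = float(r.uniform(-4.0, 0.0))
            y = r.random((n, n))
            ctx = calw.WienerContext.from_kernels(
                [kern], n, reg_bank=regs, alpha=np.array([alpha]))
            ours = calw.wiener_deconvolve(y, ctx, 0).data
            K = circulant_matrix(kern, n)
            A = K.T @ K + np.exp(alpha) * sum(
                circulant_matrix(np.asarray(g), n).T
                @ circulant_matrix(np.asarray(g), n) for g in regs)
            oracle = np.linalg.solve(A, K.T @ y.ravel()).reshape(n, n)
            worst = max(worst, float(np.abs(ours - oracle).max()))
        assert worst < 1e-5

    def test_solution_norm_non_increasing_in_alpha(self, rng):
        y = rng.random((16, 16))
        kern = centered_gaussian()
        norms = []
        for a in range(-8, 5):
            ctx = calw.WienerContext.from_kernels(
                [kern], 16, alpha=np.array([float(a)]))
            norms.append(np.linalg.norm(calw.wiener_deconvolve(y, ctx, 0).data))
        assert all(n1 >= n2 - 1e-12 for n1, n2 in zip(norms, norms[1:]))

    def test_singular_filter_detected(self):
        delta = np.zeros((3, 3))
        delta[1, 1] = 1.0
        ctx = calw.WienerContext.from_kernels(
            [delta], 8, reg_bank=np.zeros((1, 3, 3)), alpha=np.zeros(1))
        # zero out the OTF manually: zero kernel has zero spectrum everywhere
        ctx.otf = ag.Tensor(np.zeros_like(ctx.otf.data))
        with pytest.raises(calw.SingularFilterError):
            calw.wiener_deconvolve(np.ones((8, 8)), ctx, 0)

    def test_size_mismatch_rejected(self):
        ctx = calw.WienerContext.from_kernels([centered_gaussian(5)], 8)
        with pytest.raises(ValueError):
            calw.wiener_deconvolve(np.zeros((6, 6)), ctx, 0)


class TestSpectrumCorrection:
    def test_identity_at_initialization(self, rng):
        corr = calw.SpectrumCorrection(rng)
        otf = ag.fft2(ag.Tensor(centered_gaussian()))
        out = corr(otf)
        assert np.array_equal(out.data, otf.data)

    def test_corrected_dc_magnitude_stays_bounded(self, rng):
        corr = calw.SpectrumCorrection(rng)
        # drive the residual head hard; the tanh bound must still hold
        corr.head.weight.data[:] = 100.0
        corr.head.bias.data[:] = 100.0
        for seed in range(5):
            k = centered_gaussian(9, 1.0 + seed)
            out = corr(ag.fft2(ag.Tensor(k))).data
            dc = np.hypot(out[0, 0, 0], out[0, 0, 1])
            assert 0.5 - 1e-9 <= dc <= 1.5 + 1e-9

    def test_corrected_kernel_round_trip_at_init(self, rng):
        corr = calw.SpectrumCorrection(rng)
        k = centered_gaussian()
        back = corr.correct_kernel(k).data
        assert np.abs(back - k).max() < 1e-12


class TestRegKernelPredictor:
    def test_outputs_base_bank_at_initialization(self, rng):
        pred = calw.RegKernelPredictor(rng)
        y = ag.Tensor(rng.random((3, 32, 32)))
        out = pred(y).data
        assert np.array_equal(out, calw.base_reg_bank())

    def test_base_bank_kernels_kill_dc(self):
        """All base kernels are zero-sum: a constant image is unregularized
        at zero frequency."""
        bank = calw.base_reg_bank()
        sums = bank.sum(axis=(1, 2))
        assert np.abs(sums).max() < 1e-12
        spectra = np.abs(np.fft.fft2(bank, s=(16, 16)))
        assert np.abs(spectra[:, 0, 0]).max() < 1e-12

    def test_bank_becomes_content_dependent_after_an_update(self, rng):
        pred = calw.RegKernelPredictor(rng)
        y1 = ag.Tensor(rng.random((3, 16, 16)))
        y2 = ag.Tensor(rng.random((3, 16, 16)))
        # one gradient step on the head makes the residual input-dependent
        loss = (pred(y1) * pred(y1)).sum()
        loss.backward()
        pred.head.weight.data -= 0.1 * rng.random(pred.head.weight.shape)
        b1, b2 = pred(y1).data, pred(y2).data
        assert np.linalg.norm(b1 - b2) > 0


class TestCALWForward:
    def make_sample(self, psf_set, sigma=2.0, style="grating", **kw):
        gt = generate_specimen(1, size=128, style=style, **kw)
        return gt, degrade(gt, psf_set=psf_set, sigma=sigma, seed=3, margin=16)

    def delta_set(self):
        k = np.zeros((33, 33))
        k[16, 16] = 1.0
        return np.broadcast_to(k, (2, 2, 3, 33, 33)).copy()

    def test_delta_kernels_zero_bank_compose_to_identity(self, rng):
        model = calw.CALW(rng)
        model.predictor.base = np.zeros((8, 3, 3))
        _, s = self.make_sample(self.delta_set())
        y = ag.Tensor(hwc_to_chw(s.input_y))
        out = model(y, s.psf_set).data
        assert np.abs(out - y.data).max() < 1e-12

    def test_channels_are_independent(self, rng):
        gauss = np.broadcast_to(centered_gaussian(33, 2.0),
                                (2, 2, 3, 33, 33)).copy()
        _, s = self.make_sample(gauss, style="texture")
        y = ag.Tensor(hwc_to_chw(s.input_y))
        model = calw.CALW(np.random.default_rng(0))
        base = model(y, s.psf_set).data
        # perturb only the red-channel kernels: green/blue outputs unchanged
        perturbed = s.psf_set.copy()
        perturbed[:, :, 0] = self.delta_set()[:, :, 0]
        out = model(y, perturbed).data
        assert np.abs(out[1:] - base[1:]).max() < 1e-12
        assert np.abs(out[0] - base[0]).max() > 1e-6

    def test_deconvolution_beats_the_blurred_input(self, rng):
        """On a noiseless-ish blurred grating with the true kernel, the Wiener
        output is closer to the half-resolution GT than the input is."""
        gauss = np.broadcast_to(centered_gaussian(33, 2.5),
                                (2, 2, 3, 33, 33)).copy()
        gt, s = self.make_sample(gauss, sigma=2.0, style="grating", freq=14)
        model = calw.CALW(np.random.default_rng(0))
        model.alpha.data[:] = -6.0
        out = model(ag.Tensor(hwc_to_chw(s.input_y)), s.psf_set).data
        gt_half = downsample2x(hwc_to_chw(gt.pixels)).data
        assert psnr(out, gt_half) > psnr(hwc_to_chw(s.input_y), gt_half) + 1.0

    def test_alpha_gradient_matches_finite_differences(self):
        gauss = np.broadcast_to(centered_gaussian(33, 2.0),
                                (2, 2, 3, 33, 33)).copy()
        _, s = self.make_sample(gauss, style="texture")
        y = ag.Tensor(hwc_to_chw(s.input_y))

        def loss_with(alpha):
            m = calw.CALW(np.random.default_rng(1))
            m.alpha.data = alpha.copy()
            out = m(y, s.psf_set)
            return m, (out * out).mean()

        alpha0 = np.full(3, calw.ALPHA_INIT)
        model, loss = loss_with(alpha0)
        loss.backward()
        grad = model.alpha.grad.copy()
        eps = 1e-5
        for c in range(3):
            up, dn = alpha0.copy(), alpha0.copy()
            up[c] += eps
            dn[c] -= eps
            fd = (loss_with(up)[1].item() - loss_with(dn)[1].item()) / (2 * eps)
            assert abs(grad[c] - fd) <= 1e-4 * max(abs(fd), 1e-8)

    def test_spectrum_correction_recovers_a_shifted_kernel(self, rng):
        """Fitting only the correction on a sample whose true kernel is the
        dictionary kernel shifted by 1 px lowers the physics residual
        relative to keeping the correction frozen."""
        from psf4d.losses import physics_loss

        k = centered_gaussian(33, 2.0)
        true = np.roll(k, 1, axis=1)  # real optics differ from the dictionary
        true_set = np.broadcast_to(true, (2, 2, 3, 33, 33)).copy()
        dict_set = np.broadcast_to(k, (2, 2, 3, 33, 33)).copy()
        gt = generate_specimen(2, size=64, style="texture")
        s = degrade(gt, psf_set=true_set, sigma=2.0, seed=5, margin=16)
        gt_t = ag.Tensor(hwc_to_chw(s.gt_x))
        y_t = ag.Tensor(hwc_to_chw(s.input_y))

        def residual(model):
            corrected = model.calw.corrected_psf_set(dict_set)
            return physics_loss(gt_t, corrected, y_t,
                                tile=s.tile, margin=s.margin)

        from psf4d.dgnet import DegradationGuidedRestorer, NetworkConfig
        model = DegradationGuidedRestorer(NetworkConfig("tiny"), seed=0)
        frozen = residual(model).item()
        params = [(n, p) for n, p in model.named_parameters()
                  if "calw.correction" in n]
        from psf4d.training import Adam
        opt = Adam(params, lr=3e-3)
        for _ in range(25):
            for _, p in params:
                p.zero_grad()
            loss = residual(model)
            loss.backward()
            opt.step()
        assert residual(model).item() < frozen
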