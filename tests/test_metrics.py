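"""Metrology stack against independent brute-force / closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpsr.metrics import (FWHM_PER_SIGMA, N_NIQE_FEATURES, NIQEModel,
                          fit_niqe_model, frc_resolution, measure_psf_fwhm,
                          mse, niqe_score, piqe, psnr, quality_report,
                          rse_rsp, snr_db, ssim)
from mpsr.synth import (PhantomSpec, derive_masks, generate_phantom,
                        simulate_point_grid)


def brute_force_mse(a, b):
    total = 0.0
    for x, y in zip(np.ravel(a).tolist(), np.ravel(b).tolist()):
        total += (x - y) ** 2
    return total / np.asarray(a).size


class TestFullReference:
    def test_identical_images(self):
        a = np.random.default_rng(0).random((8, 8))
        assert mse(a, a) == 0.0
        assert psnr(a, a) == float("inf")
        assert ssim(a, a) == 1.0

    def test_psnr_hand_arithmetic(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[0.0, 0.5]])
        assert mse(a, b) == pytest.approx(0.125)
        assert psnr(a, b, 1.0) == pytest.approx(10 * math.log10(1 / 0.125),
                                                abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mse_psnr_match_brute_force_and_are_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random((6, 7)), rng.random((6, 7))
        assert mse(a, b) == pytest.approx(brute_force_mse(a, b), abs=1e-12)
        assert mse(a, b) == mse(b, a)
        assert psnr(a, b) == psnr(b, a)

    def test_ssim_constant_patch_matches_direct_formula(self):
        """8x8 uniform images: local means are exact, variances zero, so
        SSIM reduces to the luminance term (2*mu_x*mu_y + C1) / (...)."""
        a = np.full((8, 8), 0.5)
        b = np.full((8, 8), 0.25)
        c1 = (0.01 * 1.0) ** 2
        expected = (2 * 0.5 * 0.25 + c1) / (0.5 ** 2 + 0.25 ** 2 + c1)
        assert ssim(a, b) == pytest.approx(expected, abs=1e-12)
        assert ssim(a, b) == ssim(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            ssim(np.zeros((2, 2)), np.zeros((2, 2)))


class TestSNR:
    def _masks(self, shape=(256, 256)):
        sig = np.zeros(shape, bool)
        bg = np.zeros(shape, bool)
        sig[:64] = True
        bg[-64:] = True
        return sig, bg

    def test_equal_stds_give_zero_db(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0.5, 0.1, (256, 256))
        sig, bg = self._masks()
        assert abs(snr_db(img, sig, bg)) < 0.5

    def test_ten_to_one_std_ratio_gives_twenty_db(self):
        rng = np.random.default_rng(2)
        img = np.zeros((256, 256))
        sig, bg = self._masks()
        img[sig] = rng.normal(0.5, 0.10, sig.sum())
        img[bg] = rng.normal(0.1, 0.01, bg.sum())
        assert snr_db(img, sig, bg) == pytest.approx(20.0, abs=0.5)

    def test_added_white_noise_lowers_snr(self):
        rng = np.random.default_rng(3)
        img = np.zeros((256, 256))
        sig, bg = self._masks()
        img[sig] = rng.normal(0.5, 0.2, sig.sum())
        img[bg] = rng.normal(0.05, 0.02, bg.sum())
        before = snr_db(img, sig, bg)
        noisy = img + rng.normal(0, 0.02, img.shape)
        assert snr_db(noisy, sig, bg) < before

    def test_mask_contracts(self):
        sig, bg = self._masks()
        with pytest.raises(ValueError, match="disjoint"):
            snr_db(np.zeros((256, 256)), sig, sig)
        with pytest.raises(ValueError, match="zero variance"):
            snr_db(np.zeros((256, 256)), sig, bg)
        with pytest.raises(ValueError, match="100"):
            small = np.zeros((256, 256), bool)
            small[0, :50] = True
            snr_db(np.zeros((256, 256)), small, bg)


@pytest.fixture(scope="module")
def pristine_model():
    imgs = [generate_phantom(PhantomSpec(shape_gt=(256, 256), seed=s))[:, :, s % 3]
            for s in range(8)]
    return fit_niqe_model(imgs, patch_size=32)


class TestNIQE:
    def test_feature_dimension_matches_enumerated_set(self, pristine_model):
        """Independent enumeration: per scale, 2 GGD parameters + 4 shifted
        pairwise products x 4 AGGD parameters = 18; two scales = 36."""
        per_scale = 2 + 4 * 4
        assert N_NIQE_FEATURES == 2 * per_scale
        assert pristine_model.mean.shape == (36,)
        assert pristine_model.covariance.shape == (36, 36)

    def test_covariance_positive_semidefinite(self, pristine_model):
        eigs = np.linalg.eigvalsh(pristine_model.covariance)
        assert eigs.min() >= -1e-10

    def test_duplicated_training_images_change_nothing(self):
        imgs = [generate_phantom(PhantomSpec(shape_gt=(256, 256), seed=s))[:, :, 0]
                for s in range(3)]
        m1 = fit_niqe_model(imgs, patch_size=32)
        m2 = fit_niqe_model(imgs + imgs, patch_size=32)
        np.testing.assert_allclose(m1.mean, m2.mean, rtol=1e-8)
        # covariance uses n-1 normalisation, so duplication rescales it
        np.testing.assert_allclose(m1.covariance, m2.covariance, rtol=0.05)

    def test_deterministic_scoring(self, pristine_model):
        img = generate_phantom(PhantomSpec(shape_gt=(256, 256), seed=50))[:, :, 0]
        assert niqe_score(img, pristine_model) == niqe_score(img, pristine_model)

    def test_noise_raises_niqe_in_9_of_10_trials(self, pristine_model):
        wins = 0
        for s in range(10):
            img = generate_phantom(PhantomSpec(shape_gt=(256, 256),
                                               seed=100 + s))[:, :, s % 3]
            noisy = np.clip(img + np.random.default_rng(s).normal(
                0, 20.0 / 255.0, img.shape), 0, 1)
            wins += niqe_score(img, pristine_model) < niqe_score(noisy,
                                                                 pristine_model)
        assert wins >= 9

    def test_constant_image_fallback(self, pristine_model):
        with pytest.warns(UserWarning, match="degenerate"):
            score = niqe_score(np.full((256, 256), 0.5), pristine_model)
        assert score == 100.0

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_niqe_model([np.zeros((64, 64))])


class TestPIQE:
    def test_blur_raises_piqe_in_9_of_10_trials(self):
        from scipy.ndimage import gaussian_filter
        wins = 0
        for s in range(10):
            img = generate_phantom(PhantomSpec(shape_gt=(256, 256),
                                               seed=200 + s))[:, :, s % 3]
            blurred = gaussian_filter(img, 4.0)
            wins += piqe(blurred) > piqe(img)
        assert wins >= 9

    def test_score_range_and_constant_fallback(self):
        img = generate_phantom(PhantomSpec(shape_gt=(256, 256), seed=1))[:, :, 0]
        assert 0.0 <= piqe(img) <= 100.0
        with pytest.warns(UserWarning, match="constant"):
            assert piqe(np.full((64, 64), 0.3)) == 100.0


class TestRSERSP:
    def test_affine_intensity_invariance(self):
        ref = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=3))[:, :, 0]
        sr = np.repeat(np.repeat(ref, 4, 0), 4, 1) * 0.7 + 0.1
        rse, rsp, _ = rse_rsp(sr, ref)
        assert rse < 1e-6
        assert rsp == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_has_near_zero_rsp(self):
        ref = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=3))[:, :, 0]
        noise = np.random.default_rng(4).random((512, 512))
        _, rsp, _ = rse_rsp(noise, ref)
        assert abs(rsp) < 0.1

    def test_error_map_peaks_at_injected_artifact(self):
        ref = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=5))[:, :, 1]
        sr = np.repeat(np.repeat(ref, 4, 0), 4, 1)
        sr[200:216, 320:336] += 0.5  # localized hallucination
        _, _, emap = rse_rsp(sr, ref)
        peak = np.unravel_index(np.argmax(emap), emap.shape)
        assert 200 // 4 <= peak[0] < 216 // 4
        assert 320 // 4 <= peak[1] < 336 // 4

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant reference"):
            rse_rsp(np.random.default_rng(0).random((64, 64)),
                    np.full((16, 16), 0.5))

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            rse_rsp(np.zeros((100, 100)), np.zeros((64, 64)))


class TestFRC:
    def _band_limited(self, cutoff, shape=(256, 256), seed=0):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal(shape)
        f = np.fft.fft2(base)
        yy, xx = np.indices(shape)
        ry = np.minimum(yy, shape[0] - yy) / shape[0]
        rx = np.minimum(xx, shape[1] - xx) / shape[1]
        f[np.sqrt(ry ** 2 + rx ** 2) > cutoff] = 0
        sig = np.fft.ifft2(f).real
        return (sig - sig.min()) / (sig.max() - sig.min())

    def test_identical_images_have_unit_correlation(self):
        sig = self._band_limited(0.3)
        curve = frc_resolution(sig, sig)
        assert curve.beyond_nyquist
        assert curve.correlation.min() > 0.99
        assert math.isinf(curve.resolution_px)

    def test_independent_noise_cuts_off_immediately(self):
        a = np.random.default_rng(1).random((128, 128))
        b = np.random.default_rng(2).random((128, 128))
        curve = frc_resolution(a, b)
        # crossing within the lowest tenth of the frequency range, and the
        # correlation fluctuates around zero thereafter
        assert curve.cutoff_frequency <= 0.05
        assert abs(curve.correlation[len(curve.correlation) // 2:].mean()) < 0.05

    def test_recovers_constructed_band_limit(self):
        sig = self._band_limited(0.2)
        rng = np.random.default_rng(3)
        a = sig + rng.normal(0, 0.05, sig.shape)
        b = sig + rng.normal(0, 0.05, sig.shape)
        curve = frc_resolution(a, b, threshold=1.0 / 7.0)
        assert curve.cutoff_frequency == pytest.approx(0.2, rel=0.10)

    def test_single_image_checkerboard_split(self):
        sig = self._band_limited(0.1, seed=4)
        rng = np.random.default_rng(5)
        noisy = sig + rng.normal(0, 0.05, sig.shape)
        curve = frc_resolution(noisy)
        # half-resolution grid doubles the apparent frequency of the limit
        assert curve.cutoff_frequency is not None
        assert 0.05 < curve.cutoff_frequency <= 0.5

    def test_nm_conversion(self):
        sig = self._band_limited(0.2)
        rng = np.random.default_rng(6)
        curve = frc_resolution(sig + rng.normal(0, 0.05, sig.shape),
                               sig + rng.normal(0, 0.05, sig.shape),
                               pixel_size_nm=100.0)
        assert curve.resolution_nm == pytest.approx(
            curve.resolution_px * 100.0)


class TestPSF:
    def test_recovers_known_sigma_within_one_percent(self):
        img, centers = simulate_point_grid(25, 2.0, (256, 256), seed=0)
        res = measure_psf_fwhm(img, centers)
        assert res.mean_fwhm_px == pytest.approx(FWHM_PER_SIGMA * 2.0, rel=0.01)
        assert res.n_passed == 25

    def test_nm_unit_arithmetic(self):
        img, centers = simulate_point_grid(9, 2.0, (200, 200), seed=1)
        res = measure_psf_fwhm(img, centers, pixel_size_nm=100.0)
        assert res.mean_fwhm_nm == pytest.approx(res.mean_fwhm_px * 100.0)

    def test_noisy_spot_fails_quality_gates(self):
        """Dim spots buried in noise (SNR < 2) fail the R^2/SSE/RMSE gates
        and are excluded from the aggregate; bright spots still pass."""
        dim, dim_centers = simulate_point_grid(9, 2.0, (200, 200), seed=2,
                                               amplitude=0.2)
        bright, bright_centers = simulate_point_grid(4, 2.0, (200, 200),
                                                     seed=4, amplitude=5.0)
        rng = np.random.default_rng(3)
        combined = np.maximum(dim + rng.normal(0, 0.15, dim.shape), 0) + bright
        res = measure_psf_fwhm(combined,
                               list(bright_centers) + list(dim_centers))
        dim_keys = {tuple(c) for c in dim_centers}
        dim_fits = [s for s in res.spots if tuple(s.center) in dim_keys]
        bright_fits = [s for s in res.spots if tuple(s.center) not in dim_keys]
        # (one dim window may lock onto a neighbouring bright spot's tail)
        assert sum(not s.passed for s in dim_fits) >= len(dim_fits) - 1
        assert all(s.passed for s in bright_fits)

    def test_all_failures_raise_with_diagnostics(self):
        rng = np.random.default_rng(5)
        img = rng.random((128, 128))
        with pytest.raises(ValueError, match="gates"):
            measure_psf_fwhm(img, [(64, 64)])


class TestQualityReport:
    def test_per_channel_metrics_present(self):
        gt = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=6))
        pred = np.clip(gt + np.random.default_rng(0).normal(0, 0.02, gt.shape),
                       0, 1)
        rep = quality_report(pred, gt, channel_names=["r", "g", "b"])
        assert set(rep.channels) == {"r", "g", "b"}
        for row in rep.channels.values():
            assert {"mse", "psnr_db", "ssim", "rse", "rsp", "piqe"} <= set(row)
            assert "snr_db" in row
        assert "mask_rule" in rep.config
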