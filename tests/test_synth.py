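"""Synthetic-acquisition simulator: phantom generation, degradation physics,
fringe/lattice artefact structure, and the Poisson/read-noise calibration."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpsr.registration import PlanarTransform
from mpsr.synth import (DegradationConfig, PhantomSpec, add_scan_fringes,
                        add_stitch_lattice, degrade, derive_masks,
                        generate_phantom, identity_config, simulate_point_grid)


class TestPhantom:
    def test_zero_density_is_flat_background(self):
        spec = PhantomSpec(shape_gt=(64, 64), structure_density=0.0,
                           intensity_range=(0.05, 0.8), seed=1)
        img = generate_phantom(spec)
        np.testing.assert_allclose(img, 0.05, atol=1e-6)

    def test_determinism(self):
        spec = PhantomSpec(shape_gt=(128, 128), seed=7)
        np.testing.assert_array_equal(generate_phantom(spec),
                                      generate_phantom(spec))

    def test_structure_count_matches_placement_log(self):
        """Connected components above half-max agree with the generator's own
        placement record (coalescence makes components <= placements)."""
        from scipy.ndimage import label
        spec = PhantomSpec(shape_gt=(1024, 1024), channels=("blobs",),
                           structure_density=30.0, seed=7,
                           intensity_range=(0.0, 1.0))
        img, log = generate_phantom(spec, return_log=True)
        n_placed = len(log["blobs"])
        assert n_placed == round(30.0 * 1024 * 1024 / 1e6)
        n_comp = label(img[:, :, 0] > 0.5 * img.max())[1]
        assert 0.6 * n_placed <= n_comp <= n_placed

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            generate_phantom(PhantomSpec(shape_gt=(100, 100)))

    def test_channel_kinds_validated(self):
        with pytest.raises(ValueError, match="unknown channel"):
            generate_phantom(PhantomSpec(channels=("spirals",)))

    def test_range_and_channels(self):
        img = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=0))
        assert img.shape == (128, 128, 3)
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestDegrade:
    def test_identity_config_is_exact_identity(self):
        gt = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=2))
        pair = degrade(gt, identity_config())
        np.testing.assert_array_equal(pair.input_image, pair.gt_image)
        np.testing.assert_array_equal(pair.input_image, gt)

    def test_poisson_variance_matches_moment_identity(self):
        """Shot noise on a constant image: var == mean / gain (within 5%)."""
        m, gain = 0.25, 100.0
        const = np.full((512, 512), m, np.float32)
        pair = degrade(const, identity_config(photon_gain=gain, seed=3))
        assert pair.input_image.var() == pytest.approx(m / gain, rel=0.05)

    def test_read_noise_calibration(self):
        """Gaussian read noise at the 8-bit exemplar level: STD 20/255 on a
        constant image at the typical signal level 62/255 (within 10%)."""
        const = np.full((512, 512), 62.0 / 255.0, np.float32)
        pair = degrade(const, identity_config(read_noise_std=20.0 / 255.0, seed=4))
        assert pair.input_image.std() == pytest.approx(20.0 / 255.0, rel=0.10)

    def test_shapes_and_masks(self):
        gt = generate_phantom(PhantomSpec(shape_gt=(256, 256), seed=5))
        pair = degrade(gt, DegradationConfig(seed=5))
        assert pair.input_image.shape == (64, 64, 3)
        assert pair.gt_image.shape == (256, 256, 3)
        assert not np.logical_and(pair.signal_mask, pair.background_mask).any()
        assert np.isfinite(np.linalg.inv(pair.true_transform.matrix)).all()

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            degrade(np.full((32, 32), 1.5, np.float32), identity_config())

    def test_seeded_reproducibility(self):
        gt = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=6))
        cfg = DegradationConfig(seed=11)
        a, b = degrade(gt, cfg), degrade(gt, cfg)
        np.testing.assert_array_equal(a.input_image, b.input_image)
        np.testing.assert_array_equal(a.true_transform.matrix,
                                      b.true_transform.matrix)

    def test_misalign_override_recorded(self):
        gt = generate_phantom(PhantomSpec(shape_gt=(128, 128), seed=6))
        t = PlanarTransform.from_similarity(shift_xy=(4.0, -4.0))
        pair = degrade(gt, identity_config(downsample_factor=4,
                                           psf_fwhm_input_px=2.0), misalign=t)
        np.testing.assert_array_equal(pair.true_transform.matrix, t.matrix)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DegradationConfig(downsample_factor=0).validate()
        with pytest.raises(ValueError):
            DegradationConfig(sla_overlap=1.0).validate()
        with pytest.raises(ValueError):
            DegradationConfig(misalign_max_shift_px=300.0).validate()


class TestScanFringes:
    def test_zero_amplitude_is_identity(self):
        img = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        np.testing.assert_array_equal(add_scan_fringes(img, 0.0, 16), img)

    def test_row_profile_spectrum_peaks_at_configured_period(self):
        img = np.full((256, 256), 0.5, np.float32)
        out = add_scan_fringes(img, 0.3, 32.0, seed=1)
        row_means = out.mean(axis=1)
        spec = np.abs(np.fft.rfft(row_means - row_means.mean()))
        assert np.argmax(spec) == 256 // 32

    def test_mean_preserved_over_integer_periods(self):
        img = np.full((256, 128), 0.5, np.float32)
        out = add_scan_fringes(img, 0.3, 32.0, seed=2)
        assert out.mean() == pytest.approx(img.mean(), rel=0.01)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), amp=st.floats(0.05, 0.5),
           period=st.floats(8.0, 64.0))
    def test_fringes_are_purely_row_structured(self, seed, amp, period):
        """Column means of the (fringed / clean) ratio are constant per row,
        so the ratio has zero variance along every row."""
        img = np.full((128, 96), 0.5, np.float32)
        out = add_scan_fringes(img, amp, period, seed=seed)
        ratio = out / img
        assert float(ratio.std(axis=1).max()) < 1e-6

    def test_amplitude_bound(self):
        with pytest.raises(ValueError):
            add_scan_fringes(np.zeros((8, 8), np.float32), 1.0, 16)


class TestStitchLattice:
    def test_zero_amplitude_is_identity(self):
        img = np.random.default_rng(1).random((64, 64)).astype(np.float32)
        np.testing.assert_array_equal(
            add_stitch_lattice(img, (4, 4), 0.5, 0.0), img)

    def test_quadrant_offsets_exact_without_overlap(self):
        img = np.zeros((64, 64), np.float32)
        a = 0.1
        offsets = np.array([[a, -a], [-a, a]], np.float32)
        out = add_stitch_lattice(img, (2, 2), 0.0, 0.05, offsets=offsets)
        np.testing.assert_allclose(out[:32, :32], a, atol=1e-6)
        np.testing.assert_allclose(out[:32, 32:], -a, atol=1e-6)
        np.testing.assert_allclose(out[32:, :32], -a, atol=1e-6)
        np.testing.assert_allclose(out[32:, 32:], a, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_lattice_period_equals_field_stride(self, seed):
        """The autocorrelation of the seam-gradient profile peaks at a
        multiple of the field stride (the lattice period)."""
        img = np.zeros((512, 512), np.float32)
        out = add_stitch_lattice(img, (16, 16), 0.5, 0.1, seed=seed)
        g = np.abs(np.diff(out.mean(axis=1)))
        g = g - g.mean()
        ac = np.correlate(g, g, mode="full")[len(g) - 1:]
        stride = 512 // 16
        peak_lag = int(np.argmax(ac[stride // 2: 3 * stride])) + stride // 2
        rem = peak_lag % stride
        assert min(rem, stride - rem) <= 2

    def test_non_divisible_geometry_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            add_stitch_lattice(np.zeros((100, 100), np.float32), (16, 16),
                               0.5, 0.1)


class TestPointGrid:
    def test_zero_points_gives_empty_image(self):
        img, centers = simulate_point_grid(0, 2.0, (64, 64))
        assert img.max() == 0.0 and len(centers) == 0

    def test_integrated_intensity_matches_gaussian_integral(self):
        amp, sigma = 1.0, 2.0
        img, centers = simulate_point_grid(25, sigma, (256, 256), seed=1,
                                           amplitude=amp)
        total = img.sum() / 25
        assert total == pytest.approx(amp * 2 * np.pi * sigma ** 2, rel=0.01)

    def test_determinism(self):
        a = simulate_point_grid(9, 1.5, (128, 128), seed=3)
        b = simulate_point_grid(9, 1.5, (128, 128), seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_overcrowded_grid_rejected(self):
        with pytest.raises(ValueError, match="separated"):
            simulate_point_grid(400, 3.0, (64, 64))


class TestMasks:
    def test_masks_are_extreme_deciles(self):
        gt = generate_phantom(PhantomSpec(shape_gt=(256, 256), seed=8))
        sig, bg = derive_masks(gt)
        ref = gt.max(axis=2)
        assert ref[sig].min() >= np.quantile(ref, 0.9) - 1e-9
        assert ref[bg].max() <= np.quantile(ref, 0.1) + 1e-9
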