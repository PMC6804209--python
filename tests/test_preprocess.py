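"""Preprocessing chain: calibration, transmission, baseline, SG, crop,
normalization, and the composed pipeline."""

import numpy as np
import pytest

from ramanpipe.preprocess import (
    BaselineFitConfig,
    CalibrationTable,
    DEFAULT_REGIONS,
    PreprocessConfig,
    calibrate_axis,
    correct_transmission,
    crop_to_regions,
    minmax_normalize,
    preprocess_matrix,
    preprocess_pipeline,
    remove_baseline,
    remove_baseline_matrix,
    savitzky_golay,
)
from ramanpipe.spectra import RamanSpectrum


class TestCalibrateAxis:
    def test_two_point_line(self):
        table = CalibrationTable(pixels=[0, 1023], shifts=[500.0, 3200.0])
        cal = calibrate_axis(table, n_pixels=1024, fit_degree=1)
        assert cal.axis[0] == pytest.approx(500.0)
        assert cal.axis[-1] == pytest.approx(3200.0)
        assert np.allclose(np.diff(cal.axis), (3200.0 - 500.0) / 1023)

    def test_collinear_pairs_zero_residuals(self):
        px = np.array([0.0, 100.0, 400.0, 700.0, 1000.0])
        table = CalibrationTable(pixels=px, shifts=2.0 * px + 500.0)
        cal = calibrate_axis(table, n_pixels=1024, fit_degree=1)
        assert np.allclose(cal.residuals, 0.0, atol=1e-9)

    def test_quadratic_round_trip(self):
        coef = np.array([480.0, 2.5, 1.3e-4])  # generating polynomial
        px = np.array([0.0, 200.0, 450.0, 700.0, 1000.0])
        shifts = coef[0] + coef[1] * px + coef[2] * px**2
        cal = calibrate_axis(CalibrationTable(px, shifts), 1024, fit_degree=2)
        assert np.allclose(cal.coefficients, coef, atol=1e-9)
        assert np.allclose(cal.residuals, 0.0, atol=1e-9)

    def test_duplicate_pixels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            CalibrationTable(pixels=[0, 0, 10], shifts=[1.0, 2.0, 3.0])

    def test_degree_too_large_rejected(self):
        table = CalibrationTable(pixels=[0, 10], shifts=[1.0, 2.0])
        with pytest.raises(ValueError, match="fit_degree"):
            calibrate_axis(table, n_pixels=100, fit_degree=2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            CalibrationTable(pixels=[0], shifts=[1.0])


class TestCorrectTransmission:
    def test_identity(self, ramp_spectrum):
        out = correct_transmission(ramp_spectrum, np.ones(len(ramp_spectrum)))
        assert np.allclose(out.intensities, ramp_spectrum.intensities)

    def test_half_transmission_doubles(self, ramp_spectrum):
        out = correct_transmission(ramp_spectrum, np.full(len(ramp_spectrum), 0.5))
        assert np.allclose(out.intensities, 2.0 * ramp_spectrum.intensities)

    def test_round_trip(self, ramp_spectrum, rng):
        t = rng.uniform(0.2, 1.0, size=len(ramp_spectrum))
        attenuated = ramp_spectrum.with_intensities(ramp_spectrum.intensities * t)
        restored = correct_transmission(attenuated, t)
        assert np.allclose(restored.intensities, ramp_spectrum.intensities,
                           atol=1e-12)

    def test_nonpositive_rejected(self, ramp_spectrum):
        t = np.ones(len(ramp_spectrum))
        t[3] = 0.0
        with pytest.raises(ValueError, match="> 0"):
            correct_transmission(ramp_spectrum, t)

    def test_length_mismatch_rejected(self, ramp_spectrum):
        with pytest.raises(ValueError, match="length"):
            correct_transmission(ramp_spectrum, np.ones(3))


class TestRemoveBaseline:
    def test_pure_polynomial_removed(self):
        wn = np.linspace(500.0, 3200.0, 800)
        u = (wn - wn[0]) / (wn[-1] - wn[0])
        y = 50.0 + 30.0 * u + 10.0 * u**2 - 5.0 * u**3
        result = remove_baseline(RamanSpectrum(wn, y))
        assert result.converged
        assert np.abs(result.corrected.intensities).max() < 1e-6 * y.max()

    def test_peak_height_recovered(self):
        wn = np.linspace(500.0, 3200.0, 800)
        u = (wn - wn[0]) / (wn[-1] - wn[0])
        baseline = 20.0 + 15.0 * u + 8.0 * u**2
        height = 6.0
        peak = height * np.exp(-0.5 * ((wn - 1400.0) / 12.0) ** 2)
        result = remove_baseline(RamanSpectrum(wn, baseline + peak))
        idx = int(np.argmin(np.abs(wn - 1400.0)))
        assert result.corrected.intensities[idx] == pytest.approx(height, rel=0.05)

    def test_zero_vector(self):
        wn = np.linspace(500.0, 3200.0, 100)
        result = remove_baseline(RamanSpectrum(wn, np.zeros(100)))
        assert np.allclose(result.corrected.intensities, 0.0)
        assert np.allclose(result.baseline, 0.0)

    def test_too_short_spectrum_rejected(self):
        wn = np.linspace(500.0, 3200.0, 8)
        with pytest.raises(ValueError, match="degree"):
            remove_baseline(RamanSpectrum(wn, np.zeros(8)),
                            BaselineFitConfig(degree=9))

    def test_non_convergence_flagged(self, rng):
        wn = np.linspace(500.0, 3200.0, 800)
        y = 10.0 + rng.normal(0.0, 1.0, size=800)
        result = remove_baseline(
            RamanSpectrum(wn, y),
            BaselineFitConfig(max_iterations=2, tolerance=1e-12),
        )
        assert not result.converged
        assert result.n_iterations == 2

    def test_fit_never_exceeds_signal_after_convergence(self):
        wn = np.linspace(500.0, 3200.0, 600)
        u = (wn - wn[0]) / (wn[-1] - wn[0])
        y = 10.0 + 5.0 * u + 4.0 * np.exp(-0.5 * ((wn - 1000.0) / 15.0) ** 2)
        config = BaselineFitConfig(tolerance=1e-8, max_iterations=500)
        result = remove_baseline(RamanSpectrum(wn, y), config)
        assert result.converged
        # least-squares wiggle can overshoot the raw signal by a sliver;
        # bound it well below any peak scale
        assert np.all(result.baseline <= y + 1e-4 * (y.max() - y.min()))

    def test_idempotent_within_tolerance(self):
        wn = np.linspace(500.0, 3200.0, 600)
        u = (wn - wn[0]) / (wn[-1] - wn[0])
        y = 10.0 + 5.0 * u + 4.0 * np.exp(-0.5 * ((wn - 1000.0) / 15.0) ** 2)
        config = BaselineFitConfig(tolerance=1e-8, max_iterations=500)
        once = remove_baseline(RamanSpectrum(wn, y), config)
        twice = remove_baseline(once.corrected, config)
        change = np.abs(
            twice.corrected.intensities - once.corrected.intensities
        ).max()
        assert change < 1e-2 * y.max()

    def test_matrix_path_matches_single(self, rng):
        wn = np.linspace(500.0, 3200.0, 400)
        Y = rng.uniform(1.0, 2.0, size=(5, 400)).cumsum(axis=1) / 100.0
        corrected, baselines, conv, _ = remove_baseline_matrix(wn, Y)
        for i in range(5):
            single = remove_baseline(RamanSpectrum(wn, Y[i]))
            assert np.allclose(corrected[i], single.corrected.intensities)
            assert conv[i] == single.converged


class TestSavitzkyGolay:
    def test_cubic_preserved(self):
        wn = np.linspace(500.0, 3200.0, 300)
        y = ((wn - 1800.0) / 1000.0) ** 3
        out = savitzky_golay(RamanSpectrum(wn, y), window=21, order=3)
        assert np.allclose(out.intensities, y, atol=1e-9)

    def test_constant_preserved(self):
        wn = np.linspace(500.0, 3200.0, 100)
        out = savitzky_golay(RamanSpectrum(wn, np.full(100, 3.5)))
        assert np.allclose(out.intensities, 3.5)

    def test_even_window_rejected(self, ramp_spectrum):
        with pytest.raises(ValueError, match="odd"):
            savitzky_golay(ramp_spectrum, window=20)

    def test_order_ge_window_rejected(self, ramp_spectrum):
        with pytest.raises(ValueError, match="order"):
            savitzky_golay(ramp_spectrum, window=5, order=5)

    def test_noise_variance_reduced(self):
        wn = np.linspace(500.0, 3200.0, 512)
        reductions = []
        for seed in range(100):
            noise = np.random.default_rng(seed).normal(size=512)
            out = savitzky_golay(RamanSpectrum(wn, noise), 21, 3)
            reductions.append(out.intensities.var() < noise.var())
        assert all(reductions)

    def test_non_uniform_axis_needs_resample(self):
        wn = np.sort(np.random.default_rng(1).uniform(500.0, 3200.0, 200))
        spec = RamanSpectrum(wn, np.ones(200))
        with pytest.raises(ValueError, match="resample"):
            savitzky_golay(spec, 21, 3)
        out = savitzky_golay(spec, 21, 3, resample=True)
        assert len(out) == 200
        assert np.allclose(np.diff(np.diff(out.wavenumbers)), 0.0, atol=1e-9)


class TestCropToRegions:
    def test_full_range_identity(self, ramp_spectrum):
        out = crop_to_regions(ramp_spectrum, [(500.0, 3200.0)])
        assert np.array_equal(out.wavenumbers, ramp_spectrum.wavenumbers)

    def test_silent_region_removed(self, ramp_spectrum):
        out = crop_to_regions(ramp_spectrum, list(DEFAULT_REGIONS))
        assert not np.any((out.wavenumbers > 1700.0) & (out.wavenumbers < 2800.0))

    def test_channel_count_brute_force(self, ramp_spectrum):
        regions = [(600.0, 1500.0), (2900.0, 3100.0)]
        out = crop_to_regions(ramp_spectrum, regions)
        expected = sum(
            1 for w in ramp_spectrum.wavenumbers
            if any(lo <= w <= hi for lo, hi in regions)
        )
        assert len(out) == expected

    def test_unsorted_rejected(self, ramp_spectrum):
        with pytest.raises(ValueError, match="sorted"):
            crop_to_regions(ramp_spectrum, [(2800.0, 3000.0), (500.0, 1700.0)])

    def test_overlapping_rejected(self, ramp_spectrum):
        with pytest.raises(ValueError, match="overlap"):
            crop_to_regions(ramp_spectrum, [(500.0, 1700.0), (1600.0, 3000.0)])

    def test_empty_result_rejected(self, ramp_spectrum):
        with pytest.raises(ValueError, match="every channel"):
            crop_to_regions(ramp_spectrum, [(3200.5, 3300.0)])


class TestMinmaxNormalize:
    def test_simple(self):
        spec = RamanSpectrum([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        out = minmax_normalize(spec)
        assert np.allclose(out.intensities, [0.0, 0.5, 1.0])

    def test_already_normalized_unchanged(self, rng):
        y = rng.uniform(size=50)
        y[0], y[1] = 0.0, 1.0
        spec = RamanSpectrum(np.arange(50.0), y)
        assert np.allclose(minmax_normalize(spec).intensities, y)

    def test_affine_invariance(self, rng):
        y = rng.normal(size=80)
        wn = np.arange(80.0)
        base = minmax_normalize(RamanSpectrum(wn, y)).intensities
        for a, b in [(2.0, 5.0), (0.3, -7.0), (100.0, 0.0)]:
            out = minmax_normalize(RamanSpectrum(wn, a * y + b)).intensities
            assert np.allclose(out, base, atol=1e-12)

    def test_constant_rejected(self):
        spec = RamanSpectrum([1.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(spec)

    def test_constant_zeros_fallback(self):
        spec = RamanSpectrum([1.0, 2.0], [3.0, 3.0])
        out = minmax_normalize(spec, on_constant="zeros")
        assert np.allclose(out.intensities, 0.0)


class TestPipeline:
    def test_identity_stages_reduce_to_normalization(self, ramp_spectrum, rng):
        y = rng.uniform(1.0, 5.0, size=len(ramp_spectrum))
        spec = ramp_spectrum.with_intensities(y)
        config = PreprocessConfig(
            transmission=None, baseline=None, sg_window=None, regions=None
        )
        out = preprocess_pipeline(spec, config)
        assert np.allclose(out.intensities, minmax_normalize(spec).intensities)

    def test_output_range_is_unit_interval(self, gland_profile):
        from ramanpipe.synth import SyntheticConfig, simulate_spectrum

        spec = simulate_spectrum(gland_profile, SyntheticConfig(), seed=1)
        out = preprocess_pipeline(spec)
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0

    def test_known_band_centers_survive(self):
        """Top-2 local maxima sit within +-4 cm^-1 of the two largest bands.

        Uses a gland-class profile with two clearly dominant, well-separated
        bands so smoothing attenuation cannot reorder the ranking.
        """
        from ramanpipe.synth import (
            BAND_CENTERS, BandProfile, SyntheticConfig, simulate_spectrum,
        )

        dominant = {1004.0: 3.0, 1663.0: 2.0}
        bands = tuple(
            (c, dominant.get(c, 0.4), 14.0) for c in BAND_CENTERS
        )
        profile = BandProfile("gland", bands)
        spec = simulate_spectrum(profile, SyntheticConfig(noise_sd=0.005), seed=2)
        out = preprocess_pipeline(spec)
        y, wn = out.intensities, out.wavenumbers
        interior = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        peaks = np.nonzero(interior)[0] + 1
        top2 = wn[peaks[np.argsort(y[peaks])[-2:]]]
        for center in dominant:
            assert any(abs(w - center) <= 4.0 for w in top2)

    def test_deterministic(self, gland_profile):
        from ramanpipe.synth import SyntheticConfig, simulate_spectrum

        spec = simulate_spectrum(gland_profile, SyntheticConfig(), seed=4)
        a = preprocess_pipeline(spec)
        b = preprocess_pipeline(spec)
        assert a.intensities.tobytes() == b.intensities.tobytes()

    def test_matrix_matches_pipeline_rows(self, gland_profile):
        from ramanpipe.synth import SyntheticConfig, simulate_labeled_dataset

        ds = simulate_labeled_dataset(
            SyntheticConfig(n_spectra_per_class=2, seed=5)
        )
        config = PreprocessConfig(on_constant="zeros")
        wn, Y, _ = preprocess_matrix(ds.wavenumbers, ds.intensities, config)
        for i in range(0, ds.n_spectra, 5):
            single = preprocess_pipeline(ds.spectrum(i), config)
            assert np.allclose(Y[i], single.intensities, atol=1e-10)
            assert np.allclose(wn, single.wavenumbers)
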