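import numpy as np
import pytest

import spectraldwi as sd
from spectraldwi.signal_models import ComponentParams, DecayCurve, gaussian_signal
from spectraldwi.spectral_nnls import (
    DiffusionSpectrum,
    SpectralConfig,
    SpectralPeak,
    assign_components,
    build_dictionary,
    fit_spectrum,
    second_difference_operator,
    segment_peaks,
    spectral_fit_voxel,
)


def make_spectrum(config, lobes):
    """Spectrum with Gaussian-shaped lobes given as (center_D, width_idx, area)."""
    grid = config.grid
    s = np.zeros(config.M)
    for center, width, area in lobes:
        idx = np.arange(config.M)
        c = np.argmin(np.abs(grid - center))
        lobe = np.exp(-0.5 * ((idx - c) / width) ** 2)
        s += area * lobe / lobe.sum()
    return DiffusionSpectrum(grid, s)


class TestDictionary:
    def test_shape_and_b0_row(self, bvalues):
        config = SpectralConfig()
        A = build_dictionary(bvalues, config)
        assert A.shape == (9, 300)
        np.testing.assert_allclose(A[0], 1.0)

    def test_columns_are_exponentials(self, bvalues):
        config = SpectralConfig(M=10)
        A = build_dictionary(bvalues, config)
        np.testing.assert_allclose(A[:, 3], np.exp(-bvalues * config.grid[3]))

    def test_second_difference_rows(self):
        L = second_difference_operator(6)
        assert L.shape == (4, 6)
        np.testing.assert_array_equal(L[0, :3], [1, -2, 1])
        # second difference of a linear ramp is zero
        np.testing.assert_allclose(L @ np.arange(6.0), 0.0, atol=1e-12)


class TestFitSpectrum:
    def test_on_grid_single_exponential_unregularized(self, bvalues):
        config = SpectralConfig(lam=0.0)
        D_true = config.grid[150]
        curve = DecayCurve(bvalues, np.exp(-bvalues * D_true))
        spec = fit_spectrum(curve, config)
        assert spec.amplitudes[150] == pytest.approx(1.0, abs=1e-6)
        off = np.delete(spec.amplitudes, 150)
        assert np.abs(off).max() < 1e-6

    def test_amplitudes_nonnegative_under_noise(self, bvalues):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = np.exp(-bvalues * 0.002) + rng.normal(0, 0.05, bvalues.size)
            spec = fit_spectrum(DecayCurve(bvalues, y))
            assert np.all(spec.amplitudes >= 0)

    def test_large_lambda_flattens_curvature(self, mean_curve):
        loose = fit_spectrum(mean_curve, SpectralConfig(lam=0.0))
        tight = fit_spectrum(mean_curve, SpectralConfig(lam=1e4))
        L = second_difference_operator(300)
        assert np.linalg.norm(L @ tight.amplitudes) < \
            np.linalg.norm(L @ loose.amplitudes) / 10

    def test_smoothing_never_adds_peaks(self, mean_curve):
        counts = []
        for lam in (0.0, 0.01, 0.1, 1.0, 10.0):
            config = SpectralConfig(lam=lam)
            spec = fit_spectrum(mean_curve, config)
            counts.append(len(segment_peaks(spec, config, divisions=())))
        assert np.all(np.diff(counts) <= 0)


class TestSegmentPeaks:
    def test_single_lobe_full_fraction(self):
        config = SpectralConfig()
        spec = make_spectrum(config, [(2e-3, 3, 1.0)])
        peaks = segment_peaks(spec, config)
        assert len(peaks) == 1
        assert peaks[0].f == pytest.approx(1.0)

    def test_two_equal_lobes_split_half(self):
        config = SpectralConfig()
        spec = make_spectrum(config, [(2e-3, 3, 1.0), (0.1, 3, 1.0)])
        peaks = segment_peaks(spec, config)
        assert len(peaks) == 2
        for p in peaks:
            assert p.f == pytest.approx(0.5, abs=1e-6)

    def test_narrow_symmetric_lobe_centered(self):
        config = SpectralConfig()
        spec = make_spectrum(config, [(2e-3, 2, 1.0)])
        (peak,) = segment_peaks(spec, config)
        center = config.grid[np.argmin(np.abs(config.grid - 2e-3))]
        assert peak.D == pytest.approx(center, rel=2e-3)

    def test_straddling_lobe_is_split_at_regime_division(self):
        config = SpectralConfig()
        spec = make_spectrum(config, [(5e-3, 8, 1.0)])
        peaks = segment_peaks(spec, config)
        assert len(peaks) == 2
        assert peaks[0].D < 5e-3 <= peaks[1].D
        assert peaks[0].f + peaks[1].f == pytest.approx(1.0)

    def test_empty_spectrum(self):
        config = SpectralConfig()
        spec = DiffusionSpectrum(config.grid, np.zeros(config.M))
        assert segment_peaks(spec, config) == []


class TestAssignComponents:
    def _peak(self, D, f):
        return SpectralPeak(0, 1, f, f, D)

    def test_two_regime_assignment(self):
        fit = assign_components([self._peak(1.8e-3, 0.9), self._peak(70e-3, 0.1)])
        assert fit.tissue.f == pytest.approx(0.9)
        assert fit.vascular.f == pytest.approx(0.1)
        assert fit.tubule.f == 0.0 and fit.tubule.D == 0.0 and fit.tubule.fD == 0.0

    def test_too_slow_peak_excluded(self):
        fit = assign_components([self._peak(0.5e-3, 1.0)])
        assert fit.flag == "no_peaks"
        for name in sd.REGIMES:
            assert fit.regime(name).f == 0.0

    def test_three_regime_binning(self):
        fit = assign_components([
            self._peak(1.5e-3, 0.7), self._peak(10e-3, 0.2), self._peak(80e-3, 0.1)
        ])
        assert fit.tissue.f == pytest.approx(0.7)
        assert fit.tubule.f == pytest.approx(0.2)
        assert fit.vascular.f == pytest.approx(0.1)

    def test_peaks_within_regime_merge_area_weighted(self):
        fit = assign_components([self._peak(1.2e-3, 0.3), self._peak(2.4e-3, 0.6)])
        assert fit.tissue.f == pytest.approx(0.9)
        expected_D = (0.3 * 1.2e-3 + 0.6 * 2.4e-3) / 0.9
        assert fit.tissue.D == pytest.approx(expected_D)


class TestSpectralFitVoxel:
    def test_noiseless_three_component_recovery(self, mean_curve):
        fit = spectral_fit_voxel(mean_curve)
        for name, f_true, D_true in [("tissue", 0.6, 1.5e-3),
                                     ("tubule", 0.3, 10e-3),
                                     ("vascular", 0.1, 70e-3)]:
            r = fit.regime(name)
            assert r.f == pytest.approx(f_true, rel=0.05)
            assert r.D == pytest.approx(D_true, rel=0.06)
        assert fit.r2 > 0.999

    def test_noiseless_two_component_leaves_tubule_empty(self, bvalues):
        curve = gaussian_signal([ComponentParams(0.857, 0.0015),
                                 ComponentParams(0.143, 0.070)], bvalues)
        fit = spectral_fit_voxel(curve)
        assert fit.tubule.f == 0.0
        assert fit.tissue.f == pytest.approx(0.857, rel=0.05)
        assert fit.vascular.f == pytest.approx(0.143, rel=0.05)

    def test_fractions_never_exceed_one(self, small_cohort3):
        for sid in range(10):
            fit = spectral_fit_voxel(small_cohort3.curve(sid))
            total = sum(fit.regime(r).f for r in sd.REGIMES)
            assert 0.0 <= total <= 1.0 + 1e-9

    def test_export_units(self, mean_curve):
        row = spectral_fit_voxel(mean_curve).as_dict()
        assert row["D_tissue"] == pytest.approx(1.5, rel=0.06)  # 1e-3 mm^2/s


class TestOracleEquivalence:
    def test_augmented_nnls_matches_projected_gradient_qp(self, bvalues):
        # small-instance quadratic program solved independently by
        # accelerated projected gradient descent
        rng = np.random.default_rng(42)
        config = SpectralConfig(M=20, lam=0.1)
        A = build_dictionary(bvalues, config)
        L = second_difference_operator(config.M)
        A_aug = np.vstack([A, np.sqrt(config.lam) * L])
        y = (0.6 * np.exp(-bvalues * 0.0015) + 0.3 * np.exp(-bvalues * 0.01)
             + 0.1 * np.exp(-bvalues * 0.07))
        y_noisy = rng.normal(np.sqrt(y**2 + 4e-4), 0.02)
        spec = fit_spectrum(DecayCurve(bvalues, y_noisy), config)

        y_aug = np.concatenate([y_noisy, np.zeros(config.M - 2)])
        H = A_aug.T @ A_aug
        g = -A_aug.T @ y_aug
        step = 1.0 / np.linalg.eigvalsh(H).max()
        x = np.zeros(config.M)
        z, t = x.copy(), 1.0
        for _ in range(100000):
            x_new = np.maximum(z - step * (H @ z + g), 0.0)
            t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
            z = x_new + ((t - 1) / t_new) * (x_new - x)
            if np.abs(x_new - x).max() < 1e-13:
                x = x_new
                break
            x, t = x_new, t_new
        np.testing.assert_allclose(spec.amplitudes, x, atol=1e-6)
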