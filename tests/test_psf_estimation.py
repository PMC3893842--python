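import numpy as np
import pytest
import pywt

import usdeblur as u
from usdeblur.psf_estimation import HomomorphicConfig


class TestLogSpectrum:
    def test_unit_delta_gives_flat_zero(self):
        x = np.zeros(64)
        x[0] = 1.0
        np.testing.assert_allclose(u.log_spectrum(x), 0.0, atol=1e-10)

    def test_scaling_shifts_uniformly(self, rng):
        x = np.abs(rng.standard_normal(128)) + 0.1
        shift = u.log_spectrum(3.0 * x) - u.log_spectrum(x)
        np.testing.assert_allclose(shift, np.log(3.0), atol=1e-9)

    def test_gaussian_window_matches_closed_form(self):
        # |DFT| of a sampled Gaussian approximates sigma*sqrt(2 pi)*exp(-2 pi^2 sigma^2 f^2)
        n, sigma = 256, 8.0
        k = np.arange(n)
        x = np.exp(-((k - 128.0) ** 2) / (2 * sigma**2))
        ls = u.log_spectrum(x, n)
        m = np.arange(1, 16)
        expected = np.log(sigma * np.sqrt(2 * np.pi)) - 2 * np.pi**2 * sigma**2 * (m / n) ** 2
        np.testing.assert_allclose(ls[1:16], expected, atol=1e-2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            u.log_spectrum(np.zeros(32))


class TestSigmaAndThreshold:
    def test_sigma_examples(self):
        assert u.estimate_sigma(np.zeros(10)) == 0.0
        assert abs(u.estimate_sigma(np.array([-0.6745, 0.6745])) - 1.0) < 1e-12

    def test_sigma_consistent_for_gaussian_draws(self):
        d = np.random.default_rng(0).standard_normal(100_000)
        assert 0.99 <= u.estimate_sigma(d) <= 1.01

    def test_sigma_empty_rejected(self):
        with pytest.raises(ValueError):
            u.estimate_sigma(np.array([]))

    def test_universal_threshold_values(self):
        assert u.universal_threshold(0.0, 100) == 0.0
        assert abs(u.universal_threshold(1.0, np.e) - np.sqrt(2.0)) < 1e-12
        assert abs(u.universal_threshold(1.0, 1024) - np.sqrt(2 * np.log(1024))) < 1e-12
        with pytest.raises(ValueError):
            u.universal_threshold(1.0, 1)


class TestDenoise:
    def test_smooth_input_passes_through(self):
        k = np.arange(256)
        x = 3.0 + np.cos(2 * np.pi * k / 256) + 0.5 * np.cos(4 * np.pi * k / 256)
        out = u.denoise_logspectrum(x)
        assert np.sqrt(np.mean((out - x) ** 2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_denoising_gain_on_noisy_smooth_signal(self):
        rng = np.random.default_rng(3)
        k = np.arange(512)
        smooth = 2.0 * np.cos(2 * np.pi * k / 512)
        noisy = smooth + 0.3 * rng.standard_normal(512)
        out = u.denoise_logspectrum(noisy)
        assert np.mean((out - smooth) ** 2) < np.mean((noisy - smooth) ** 2)

    def test_zero_maps_to_zero(self):
        np.testing.assert_allclose(u.denoise_logspectrum(np.zeros(256)), 0.0, atol=1e-12)

    def test_details_are_non_expansive(self, rng):
        cfg = HomomorphicConfig(n_levels=4)
        x = rng.standard_normal(256)
        out = u.denoise_logspectrum(x, cfg)
        cin = pywt.wavedec(x, cfg.wavelet_name, level=4, mode="periodization")
        cout = pywt.wavedec(out, cfg.wavelet_name, level=4, mode="periodization")
        for di, do in zip(cin[1:], cout[1:]):
            assert np.all(np.abs(do) <= np.abs(di) + 1e-10)

    def test_untransformable_length_rejected(self):
        with pytest.raises(ValueError):
            u.denoise_logspectrum(np.zeros(100), HomomorphicConfig(n_levels=5))


class TestMinimumPhase:
    def test_flat_logmag_gives_delta(self):
        spec = u.min_phase_from_logmag(np.zeros(64))
        np.testing.assert_allclose(spec, 1.0, atol=1e-12)
        h = np.fft.ifft(spec).real
        assert abs(h[0] - 1.0) < 1e-12 and np.all(np.abs(h[1:]) < 1e-12)

    def test_magnitude_preserved(self, rng):
        lm = rng.standard_normal(128)
        lm = 0.5 * (lm + np.concatenate(([lm[0]], lm[:0:-1])))  # even symmetry
        spec = u.min_phase_from_logmag(lm)
        np.testing.assert_allclose(np.abs(spec), np.exp(lm), rtol=1e-9)

    def test_recovers_known_minimum_phase_system(self):
        # H(z) = 1/(1 - 0.5 z^-1) sampled on the unit circle is minimum-phase
        n = 256
        w = 2 * np.pi * np.arange(n) / n
        h_true = 1.0 / (1.0 - 0.5 * np.exp(-1j * w))
        spec = u.min_phase_from_logmag(np.log(np.abs(h_true)))
        np.testing.assert_allclose(np.angle(spec), np.angle(h_true), atol=1e-3)
        np.testing.assert_allclose(spec, h_true, atol=1e-3)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            u.min_phase_from_logmag(np.zeros(63))


class TestEstimatePSF:
    def test_self_recovery_from_single_scatter(self):
        cfg = u.SimConfig(density=1.0 / 512, snr_db=None, seed=3)
        rf, truth, psf = u.simulate_rf_line(cfg)
        est = u.normalize_psf_envelope(u.estimate_psf(u.envelope(rf)))
        true_env = u.normalize_psf_envelope(psf)
        a = est.samples / np.linalg.norm(est.samples)
        b = true_env.samples / np.linalg.norm(true_env.samples)
        assert np.correlate(a, b, mode="full").max() >= 0.95

    def test_width_recovered_within_oracle_band(self):
        # per-line -3 dB widths fluctuate with reflectivity-spectrum leakage;
        # band calibrated on oracle runs of this estimator
        def width(p):
            return np.sum(p / p.max() > 10 ** (-3 / 20))

        ratios = []
        for r in range(10):
            cfg = u.SimConfig(density=0.02, snr_db=21.0, seed=700 + r)
            rf, truth, psf = u.simulate_rf_line(cfg)
            est = u.normalize_psf_envelope(u.estimate_psf(u.envelope(rf)))
            ratios.append(width(est.samples) / width(u.normalize_psf_envelope(psf).samples))
        assert np.mean(ratios) < 1.6
        assert max(ratios) < 2.2 and min(ratios) > 0.5

    def test_scale_invariance_of_normalized_estimate(self):
        cfg = u.SimConfig(density=0.05, snr_db=21.0, seed=8)
        rf, _, _ = u.simulate_rf_line(cfg)
        env = u.envelope(rf).samples
        a = u.estimate_psf(env).samples
        b = u.estimate_psf(37.0 * env).samples
        assert a.size == b.size
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_all_zero_envelope_rejected(self):
        with pytest.raises(ValueError):
            u.estimate_psf(np.zeros(512))
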