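import math

import numpy as np
import pytest

from preictal.exceptions import ConfigurationError
from preictal.features import (
    Window,
    autocorrelation,
    feature_vector,
    power_spectral_density,
    spectral_centroid,
    spectral_skewness,
    statistical_moments,
    variational_coefficient,
    window_signal,
)

FS = 256


def _win(samples):
    return Window(samples=np.asarray(samples, float), start_s=0.0, index=0)


# -- independent brute-force oracles ----------------------------------------

def _moments_oracle(x):
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sigma = math.sqrt(var)
    if sigma == 0:
        return mu, 0.0, 0.0, 0.0
    beta = sum(((v - mu) / sigma) ** 3 for v in x) / n
    kappa = sum(((v - mu) / sigma) ** 4 for v in x) / n
    return mu, sigma, beta, kappa


def _autocorr_oracle(x):
    n = len(x)
    return np.array([
        sum(x[m] * x[m + k] for m in range(n - k)) / n for k in range(n)
    ])


def _spectral_oracle(P):
    w = np.arange(len(P))
    total = P.sum()
    c = (w * P).sum() / total
    s2 = (((w - c) ** 2) * P).sum() / total
    b = ((((w - c) / math.sqrt(s2)) ** 3) * P).sum() / total if s2 > 0 else 0.0
    return c, s2, b


class TestWindowSignal:
    def test_floor_division_discards_tail(self):
        windows = window_signal(np.arange(1000.0), FS)
        assert len(windows) == 3
        np.testing.assert_array_equal(windows[2].samples,
                                      np.arange(512.0, 768.0))

    def test_exactly_one_window(self):
        assert len(window_signal(np.zeros(256), FS)) == 1

    def test_one_sample_short_rejected(self):
        with pytest.raises(ConfigurationError):
            window_signal(np.zeros(255), FS)

    def test_start_times_and_indices(self):
        windows = window_signal(np.zeros(3 * FS), FS)
        assert [w.index for w in windows] == [0, 1, 2]
        assert [w.start_s for w in windows] == [0.0, 1.0, 2.0]


class TestStatisticalMoments:
    def test_zeros(self):
        assert statistical_moments(_win(np.zeros(10))) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_computed_small_window(self):
        mu, sigma, beta, _ = statistical_moments(_win([1.0, 2.0, 3.0, 4.0]))
        assert mu == 2.5
        assert sigma == pytest.approx(math.sqrt(1.25))
        assert beta == pytest.approx(0.0, abs=1e-12)  # symmetric

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(128)
        got = statistical_moments(_win(x))
        np.testing.assert_allclose(got, _moments_oracle(list(x)), rtol=1e-12)

    def test_excess_kurtosis_option(self, rng):
        x = rng.standard_normal(64)
        plain = statistical_moments(_win(x))[3]
        excess = statistical_moments(_win(x), excess_kurtosis=True)[3]
        assert excess == pytest.approx(plain - 3.0)


class TestAutocorrelation:
    def test_white_noise_decorrelates(self, rng):
        x = rng.standard_normal(1024)
        r = autocorrelation(_win(x))
        assert r[0] == pytest.approx(np.mean(x**2), rel=1e-10)
        assert np.max(np.abs(r[1:20])) < 0.2 * r[0]

    def test_constant_window_closed_form(self):
        c, n = 3.0, 32
        r = autocorrelation(_win(np.full(n, c)))
        expected = c**2 * (n - np.arange(n)) / n
        np.testing.assert_allclose(r, expected, rtol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal(64)
        np.testing.assert_allclose(
            autocorrelation(_win(x)), _autocorr_oracle(list(x)),
            rtol=1e-10, atol=1e-12,
        )

    def test_lag_zero_dominates(self, rng):
        r = autocorrelation(_win(rng.standard_normal(256)))
        assert np.all(r[0] >= np.abs(r) - 1e-12)


class TestPowerSpectralDensity:
    def test_sinusoid_peaks_at_its_bin(self):
        t = np.arange(FS) / FS
        psd = power_spectral_density(_win(np.sin(2 * np.pi * 16 * t)))
        assert np.argmax(psd) == 16

    def test_zero_window_gives_zero_psd(self):
        np.testing.assert_array_equal(
            power_spectral_density(_win(np.zeros(FS))), 0.0
        )

    def test_wiener_khinchin_equivalence(self, rng):
        x = rng.standard_normal(FS)
        psd = power_spectral_density(_win(x))
        periodogram = np.abs(np.fft.rfft(x)) ** 2 / FS
        np.testing.assert_allclose(psd, periodogram, rtol=1e-8,
                                   atol=1e-8 * periodogram.max())


class TestSpectralMoments:
    def test_point_mass_centroid(self):
        P = np.zeros(64)
        P[10] = 2.0
        assert spectral_centroid(P) == 10.0
        assert variational_coefficient(P, 10.0) == 0.0

    def test_symmetric_two_bin_psd(self):
        P = np.zeros(64)
        P[4] = P[12] = 1.0
        c = spectral_centroid(P)
        assert c == 8.0
        assert variational_coefficient(P, c) == 16.0
        assert spectral_skewness(P, c, 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_right_skewed_mass_positive_by_hand(self):
        P = np.zeros(16)
        P[2], P[10] = 0.75, 0.25
        c = spectral_centroid(P)
        s2 = variational_coefficient(P, c)
        got = spectral_skewness(P, c, math.sqrt(s2))
        # hand computation: c = 4, s2 = 12, terms (-2/sqrt(12))^3*0.75 + (6/sqrt(12))^3*0.25
        assert c == 4.0
        assert s2 == 12.0
        expected = ((-2 / math.sqrt(12)) ** 3 * 0.75
                    + (6 / math.sqrt(12)) ** 3 * 0.25)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0

    def test_random_psd_matches_oracle(self, rng):
        P = rng.uniform(0, 1, 129)
        c = spectral_centroid(P)
        s2 = variational_coefficient(P, c)
        b = spectral_skewness(P, c, math.sqrt(s2))
        oc, os2, ob = _spectral_oracle(P)
        assert c == pytest.approx(oc, rel=1e-12)
        assert s2 == pytest.approx(os2, rel=1e-12)
        assert b == pytest.approx(ob, rel=1e-10, abs=1e-12)


class TestFeatureVector:
    def test_constant_window_flagged(self):
        fv = feature_vector(_win(np.full(FS, 7.0)))
        assert fv.degenerate
        np.testing.assert_array_equal(fv.as_array(),
                                      [7.0, 0, 0, 0, 0, 0, 0])

    def test_sinusoid_closed_forms(self):
        t = np.arange(FS) / FS
        amp = 30.0
        fv = feature_vector(_win(amp * np.sin(2 * np.pi * 16 * t)))
        assert fv.sigma_t == pytest.approx(amp / math.sqrt(2), rel=0.02)
        assert fv.C_s == pytest.approx(16.0, abs=0.01)

    def test_vector_length_is_seven(self, rng):
        assert feature_vector(_win(rng.standard_normal(FS))).as_array().size == 7

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(FS)
        base = feature_vector(_win(x))
        scaled = feature_vector(_win(3.5 * x))
        assert scaled.mu_t == pytest.approx(3.5 * base.mu_t, rel=1e-9, abs=1e-12)
        assert scaled.sigma_t == pytest.approx(3.5 * base.sigma_t, rel=1e-9)
        for name in ("beta_t", "kappa_t", "C_s", "sigma_s2", "beta_s"):
            assert getattr(scaled, name) == pytest.approx(getattr(base, name),
                                                          rel=1e-8)

    def test_shift_moves_only_the_mean_among_time_moments(self, rng):
        x = rng.standard_normal(FS)
        base = feature_vector(_win(x))
        shifted = feature_vector(_win(x + 10.0))
        assert shifted.mu_t == pytest.approx(base.mu_t + 10.0, rel=1e-9)
        for name in ("sigma_t", "beta_t", "kappa_t"):
            assert getattr(shifted, name) == pytest.approx(getattr(base, name),
                                                           rel=1e-8)

    def test_finite_on_synthetic_windows(self, quiet_session):
        rec, _ = quiet_session
        x = rec.samples[0, : 10 * FS]
        for w in window_signal(x, FS):
            assert np.all(np.isfinite(feature_vector(w).as_array()))
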