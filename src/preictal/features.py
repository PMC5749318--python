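"""Windowing and the seven-moment feature vector.

The denoised surrogate signal is cut into nonoverlapping 1-second windows
(256 samples at the default rate). Each window yields four time-domain
statistical moments — mean, standard deviation, skewness, kurtosis, all in
population (divisor-N) form — and three spectral moments of its correlogram
power spectral density: the spectral centroid, the variational coefficient
(power-weighted variance of frequency) and the spectral skewness. Spectral
moments are computed in bin-index units over the one-sided bins 0..N/2; one
bin equals fs/N Hz.

The PSD is the Fourier transform of the biased sample autocorrelation over
the full two-sided lag range, which is algebraically identical to the
periodogram |DFT(y)|^2 / N at the same bins (Wiener-Khinchin); tiny negative
floating-point residues are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError


@dataclass
class Window:
    """One fixed-length analysis window of the surrogate signal."""

    samples: np.ndarray
    start_s: float
    index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()


@dataclass
class FeatureVector:
    """The 7 moments of one window, in the canonical order.

    ``degenerate`` flags constant windows, for which the standardized moments
    are undefined and reported as 0.
    """

    mu_t: float
    sigma_t: float
    beta_t: float
    kappa_t: float
    C_s: float
    sigma_s2: float
    beta_s: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mu_t, self.sigma_t, self.beta_t, self.kappa_t,
             self.C_s, self.sigma_s2, self.beta_s]
        )


def _samples(window) -> np.ndarray:
    return window.samples if isinstance(window, Window) else np.asarray(window, float)


def window_signal(signal: np.ndarray, fs: float) -> list[Window]:
    """Cut a signal into nonoverlapping windows of exactly ``fs`` samples.

    Window ``i`` covers samples ``[i*fs, (i+1)*fs)``; trailing samples that do
    not fill a window are discarded.
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = int(round(fs))
    if n <= 0:
        raise ConfigurationError("fs must be positive")
    if x.size < n:
        raise ConfigurationError(
            f"signal of {x.size} samples is shorter than one {n}-sample window"
        )
    n_windows = x.size // n
    return [
        Window(samples=x[i * n : (i + 1) * n], start_s=i * n / fs, index=i)
        for i in range(n_windows)
    ]


def statistical_moments(window, excess_kurtosis: bool = False):
    """Population mean, standard deviation, skewness and kurtosis.

    All moments use divisor N. Kurtosis is the standardized fourth moment
    (3 for a Gaussian); pass ``excess_kurtosis=True`` to subtract 3. Constant
    windows return zero skewness and kurtosis.
    """
    x = _samples(window)
    if x.size < 2:
        raise ConfigurationError("window needs at least 2 samples")
    mu = float(np.mean(x))
    centered = x - mu
    sigma = float(np.sqrt(np.mean(centered**2)))
    if sigma == 0:
        return mu, 0.0, 0.0, 0.0
    z = centered / sigma
    beta = float(np.mean(z**3))
    kappa = float(np.mean(z**4))
    if excess_kurtosis:
        kappa -= 3.0
    return mu, sigma, beta, kappa


def autocorrelation(window) -> np.ndarray:
    """Biased sample autocorrelation r[k] = (1/N) sum_m y[m] y[m+k], k < N.

    The 1/N normalization (rather than 1/(N-k)) keeps the sequence
    nonnegative-definite, hence the PSD nonnegative up to roundoff.
    """
    y = _samples(window)
    n = y.size
    if n < 2:
        raise ConfigurationError("window needs at least 2 samples")
    F = np.fft.rfft(y, 2 * n)
    r = np.fft.irfft(F * np.conj(F), 2 * n)[:n]
    return r / n


def power_spectral_density(window) -> np.ndarray:
    """Correlogram PSD over the one-sided bins w = 0 .. N/2.

    P(w_j) = r[0] + 2 sum_{k>=1} r[k] cos(2 pi j k / N), i.e. the two-sided
    lag transform of the biased autocorrelation, which equals the periodogram
    |DFT(y)|^2 / N exactly. Negative roundoff residues are clamped to 0.
    """
    r = autocorrelation(window)
    P = 2.0 * np.real(np.fft.rfft(r)) - r[0]
    return np.maximum(P, 0.0)


def spectral_centroid(psd: np.ndarray) -> float:
    """Power-weighted mean bin index; 0 for an all-zero PSD."""
    P = np.asarray(psd, dtype=float)
    total = P.sum()
    if total <= 0:
        return 0.0
    w = np.arange(P.size)
    return float((w * P).sum() / total)


def variational_coefficient(psd: np.ndarray, C_s: float) -> float:
    """Power-weighted variance of the bin index around the centroid."""
    P = np.asarray(psd, dtype=float)
    total = P.sum()
    if total <= 0:
        return 0.0
    w = np.arange(P.size)
    return float((((w - C_s) ** 2) * P).sum() / total)


def spectral_skewness(psd: np.ndarray, C_s: float, sigma_s: float) -> float:
    """Power-weighted standardized third moment of the bin index.

    A PSD whose spread is at the roundoff floor (sigma_s^2 below about
    eps * n_bins^2, e.g. a pure sinusoid whose off-peak bins are only
    floating-point residue) is treated as a point mass and returns 0.
    """
    P = np.asarray(psd, dtype=float)
    total = P.sum()
    floor2 = 1e3 * np.finfo(float).eps * P.size**2
    if total <= 0 or sigma_s**2 <= floor2:
        return 0.0
    w = np.arange(P.size)
    return float(((((w - C_s) / sigma_s) ** 3) * P).sum() / total)


def bin_to_hz(bin_index: float, n: int, fs: float) -> float:
    """Convert a spectral bin index (over an N-sample window) to Hz."""
    return bin_index * fs / n


def feature_vector(window, excess_kurtosis: bool = False) -> FeatureVector:
    """All seven moments of one window in the canonical order."""
    x = _samples(window)
    mu, sigma, beta, kappa = statistical_moments(x, excess_kurtosis=excess_kurtosis)
    if sigma == 0:
        return FeatureVector(mu, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    psd = power_spectral_density(x)
    c_s = spectral_centroid(psd)
    s2 = variational_coefficient(psd, c_s)
    b_s = spectral_skewness(psd, c_s, float(np.sqrt(s2)))
    return FeatureVector(mu, sigma, beta, kappa, c_s, s2, b_s)
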