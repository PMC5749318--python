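"""Synthetic labeled scalp-EEG sessions.

Each session emulates the recording geometry the pipeline assumes — 23
channels sampled at 256 Hz, roughly hour-long sessions, seizure onset no
earlier than 20 minutes in — with a latent-source model: every clinical state
drives one narrowband oscillation (configurable center frequency, bandwidth
and RMS amplitude in microvolts) through a fixed spatial mixing pattern, on
top of per-channel pink (1/f) broadband noise high-passed at 0.5 Hz the way an
acquisition chain would. State transitions are instantaneous at interval
boundaries so window labels are unambiguous.

Default spectra: a 2.5 Hz / 20 uV delta-band interictal background, a
5 Hz / 35 uV theta-band preictal shift with a more focal scalp topography, a
9 Hz / 50 uV ictal discharge (at least twice the interictal amplitude), and an
attenuated postictal background. The preictal and interictal states thus
differ in frequency content, amplitude and spatial pattern — the three handles
the CSP + moment-feature pipeline is designed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .exceptions import ConfigurationError
from .io import Recording, StateAnnotation

#: Minimum onset time (minutes) when a seizure is present, mirroring the
#: session-eligibility rule of the evaluation protocol.
MIN_ONSET_MINUTES = 20.0


@dataclass(frozen=True)
class StateSpectrum:
    """Narrowband signature of one state: center (Hz), bandwidth (Hz), RMS (uV)."""

    center_hz: float
    bandwidth_hz: float
    amplitude_uv: float


DEFAULT_STATE_SPECTRA: dict[str, StateSpectrum] = {
    "interictal": StateSpectrum(2.5, 1.5, 20.0),
    "preictal": StateSpectrum(5.0, 2.0, 35.0),
    "ictal": StateSpectrum(9.0, 4.0, 50.0),
    "postictal": StateSpectrum(2.5, 1.5, 10.0),
}

#: Which latent mixing column each state drives.
_STATE_SOURCE = {"interictal": 0, "preictal": 1, "ictal": 2, "postictal": 0}


def default_channel_mixing(n_channels: int) -> np.ndarray:
    """Mixing matrix (channels x 3 sources): diffuse background, focal
    preictal source, broader ictal source."""
    ch = np.arange(n_channels)
    focus = n_channels // 3
    background = np.ones(n_channels)
    pre = np.exp(-0.5 * ((ch - focus) / 2.5) ** 2)
    ict = np.exp(-0.5 * ((ch - focus) / 5.0) ** 2)
    return np.column_stack([background, pre, ict])


@dataclass
class SynthConfig:
    """Study conditions for one generated session."""

    n_channels: int = 23
    fs: float = 256.0
    session_minutes: float = 60.0
    onset_minute: float | None = 40.0  # None -> seizure-free session
    preictal_minutes: float = 20.0
    ictal_minutes: float = 1.0
    state_spectra: Mapping[str, StateSpectrum] = field(
        default_factory=lambda: dict(DEFAULT_STATE_SPECTRA)
    )
    noise_sd: float = 5.0
    channel_mixing: np.ndarray | None = None
    seed: int = 0
    subject_id: str = "S00"
    session_id: str = "s00"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")
        if self.session_minutes <= 0:
            raise ConfigurationError("session duration must be positive")
        if self.noise_sd < 0 or self.ictal_minutes < 0:
            raise ConfigurationError("negative durations or noise scale")
        if self.onset_minute is not None:
            if self.onset_minute < MIN_ONSET_MINUTES:
                raise ConfigurationError(
                    f"seizure onset must be >= {MIN_ONSET_MINUTES} minutes into "
                    f"the session, got {self.onset_minute}"
                )
            if self.onset_minute >= self.session_minutes:
                raise ConfigurationError("onset lies beyond the session end")
            if self.preictal_minutes <= 0 or self.preictal_minutes >= self.onset_minute:
                raise ConfigurationError(
                    "preictal duration must be positive and shorter than the onset time"
                )
        if self.channel_mixing is not None:
            m = np.asarray(self.channel_mixing, dtype=float)
            if m.shape != (self.n_channels, 3):
                raise ConfigurationError(
                    f"channel_mixing must be ({self.n_channels}, 3), got {m.shape}"
                )

    def state_intervals(self) -> list[tuple[float, float, str]]:
        """The session's interictal -> preictal -> ictal -> postictal timeline."""
        total = self.session_minutes * 60.0
        if self.onset_minute is None:
            return [(0.0, total, "interictal")]
        onset = self.onset_minute * 60.0
        pre_start = onset - self.preictal_minutes * 60.0
        ictal_end = min(onset + self.ictal_minutes * 60.0, total)
        out = []
        if pre_start > 0:
            out.append((0.0, pre_start, "interictal"))
        out.append((pre_start, onset, "preictal"))
        out.append((onset, ictal_end, "ictal"))
        if ictal_end < total:
            out.append((ictal_end, total, "postictal"))
        return out


def _narrowband(rng: np.random.Generator, n: int, fs: float,
                spec: StateSpectrum) -> np.ndarray:
    """Band-limited Gaussian noise with the requested center/bandwidth/RMS."""
    white = rng.standard_normal(n)
    lo = max(spec.center_hz - spec.bandwidth_hz / 2.0, 0.1)
    hi = min(spec.center_hz + spec.bandwidth_hz / 2.0, 0.95 * fs / 2.0)
    if hi <= lo:
        hi = lo * 1.1
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, white)
    sd = np.std(x)
    if sd > 0:
        x = x * (spec.amplitude_uv / sd)
    return x


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                corner_hz: float = 0.5) -> np.ndarray:
    """Unit-RMS 1/f noise, flat below ``corner_hz`` (acquisition high-pass)."""
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, corner_hz))
    shape[0] = 0.0
    x = np.fft.irfft(F * shape, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_session(config: SynthConfig) -> tuple[Recording, StateAnnotation]:
    """Generate one labeled session. Identical seeds give identical samples."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(fs * 60.0 * config.session_minutes))
    intervals = config.state_intervals()
    mixing = (
        np.asarray(config.channel_mixing, dtype=float)
        if config.channel_mixing is not None
        else default_channel_mixing(config.n_channels)
    )
    samples = np.zeros((config.n_channels, n))
    for start_s, end_s, label in intervals:
        i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
        if i1 <= i0:
            continue
        spec = config.state_spectra[label]
        source = _narrowband(rng, i1 - i0, fs, spec)
        samples[:, i0:i1] += np.outer(mixing[:, _STATE_SOURCE[label]], source)
    for c in range(config.n_channels):
        samples[c] += config.noise_sd * _pink_noise(rng, n, fs)

    recording = Recording(
        samples=samples,
        fs=fs,
        channel_names=[f"EEG {i + 1:02d}" for i in range(config.n_channels)],
        subject_id=config.subject_id,
        session_id=config.session_id,
    )
    onsets = [] if config.onset_minute is None else [config.onset_minute * 60.0]
    return recording, StateAnnotation(intervals=intervals, onsets=onsets)


def generate_cohort(
    n_subjects: int,
    base_config: SynthConfig | None = None,
    seed: int = 0,
    sessions_per_subject: int = 2,
) -> list[tuple[Recording, StateAnnotation]]:
    """Generate a cohort with per-subject jittered spectra.

    Each subject's state center frequencies are jittered by up to +-10% and
    amplitudes by up to +-10% around the base configuration, emulating
    between-subject variability; sessions within a subject share the subject's
    spectra but use independent noise. Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ConfigurationError("need at least one subject")
    if sessions_per_subject < 1:
        raise ConfigurationError("need at least one session per subject")
    if base_config is None:
        base_config = SynthConfig()
    master = np.random.default_rng(seed)
    sessions: list[tuple[Recording, StateAnnotation]] = []
    for si in range(n_subjects):
        jitter = {
            label: StateSpectrum(
                center_hz=spec.center_hz * (1.0 + 0.1 * master.uniform(-1, 1)),
                bandwidth_hz=spec.bandwidth_hz,
                amplitude_uv=spec.amplitude_uv * (1.0 + 0.1 * master.uniform(-1, 1)),
            )
            for label, spec in base_config.state_spectra.items()
        }
        for sj in range(sessions_per_subject):
            cfg = replace(
                base_config,
                state_spectra=jitter,
                seed=int(master.integers(0, 2**31 - 1)),
                subject_id=f"S{si:02d}",
                session_id=f"S{si:02d}r{sj}",
            )
            sessions.append(generate_session(cfg))
    return sessions
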