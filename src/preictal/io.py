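"""Recordings, state annotations and file I/O.

Recordings travel as channels x time arrays in microvolts. On disk they are
European Data Format (EDF) files; seizure annotations use the CHB-MIT style of
plain-text summary (one block per file listing seizure start/end seconds);
feature tables are CSV. Reading EDF goes through :mod:`mne`; writing uses a
minimal 16-bit EDF encoder because the scientific stack bundles no EDF writer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, UnsupportedFormatError

#: The four clinical states of a seizure cycle, in temporal order around an event.
STATES = ("interictal", "preictal", "ictal", "postictal")

FEATURE_COLUMNS = ["mu_t", "sigma_t", "beta_t", "kappa_t", "C_s", "sigma_s2", "beta_s"]


@dataclass
class Recording:
    """A multichannel sampled signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts, channel-major.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One label per channel, in row order.
    subject_id, session_id : str
        Identifiers carried through the pipeline for bookkeeping.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = "S00"
    session_id: str = "s00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be a 2-D channels x time array")
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs


@dataclass
class StateAnnotation:
    """Labeled state intervals and seizure onsets for one session.

    ``intervals`` is a list of ``(start_s, end_s, label)`` with times in seconds
    from session start; labels come from :data:`STATES`. ``onsets`` lists
    seizure-onset times; each must coincide with the start of an ictal interval.
    When ``onsets`` is omitted it is derived from the ictal intervals.
    """

    intervals: list[tuple[float, float, str]]
    onsets: list[float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), str(lab)) for s, e, lab in self.intervals]
        for s, e, lab in ivs:
            if lab not in STATES:
                raise ConfigurationError(f"unknown state label {lab!r}")
            if s < 0 or e <= s:
                raise ConfigurationError(f"bad interval ({s}, {e})")
        ivs.sort(key=lambda iv: iv[0])
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0 - 1e-9:
                raise ConfigurationError("intervals overlap")
        self.intervals = ivs
        ictal_starts = [s for s, _, lab in ivs if lab == "ictal"]
        if self.onsets is None:
            self.onsets = ictal_starts
        else:
            self.onsets = sorted(float(t) for t in self.onsets)
            for t in self.onsets:
                if not any(abs(t - s) < 1e-6 for s in ictal_starts):
                    raise ConfigurationError(
                        f"onset {t} s does not start an ictal interval"
                    )

    @property
    def duration_s(self) -> float:
        return max((e for _, e, _ in self.intervals), default=0.0)

    @property
    def has_seizure(self) -> bool:
        return len(self.onsets) > 0

    def intervals_for(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def label_at(self, t: float) -> str | None:
        """State label at time ``t`` (seconds), or None outside all intervals."""
        for s, e, lab in self.intervals:
            if s <= t < e:
                return lab
        return None


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_SIG_FIELDS = 16 + 80 + 8 + 8 + 8 + 8 + 8 + 80  # bytes per signal before srate


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as a 16-bit EDF file with 1-second records.

    The physical dimension is microvolts and per-channel calibration spans the
    channel's observed range, so the round trip is exact up to 16-bit
    quantization. Sessions are padded with zeros to a whole number of seconds.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedFormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    nch = recording.n_channels
    n_records = max(1, math.ceil(recording.n_times / fs))
    data = np.zeros((nch, n_records * fs))
    data[:, : recording.n_times] = recording.samples

    # Re-parse the formatted physical range so scaling matches the file exactly.
    pmin_s, pmax_s, digital = [], [], []
    for row in data:
        lo, hi = float(row.min()), float(row.max())
        if hi - lo < 1e-12:
            hi = lo + 1.0
        lo_s, hi_s = f"{lo:.6g}"[:8], f"{hi:.6g}"[:8]
        lo_f, hi_f = float(lo_s), float(hi_s)
        if hi_f <= lo_f:  # formatting collapsed the range
            hi_f = lo_f + 1.0
            hi_s = f"{hi_f:.6g}"[:8]
        scale = (32767 - (-32768)) / (hi_f - lo_f)
        dig = np.clip(np.round((row - lo_f) * scale) - 32768, -32768, 32767)
        pmin_s.append(lo_s)
        pmax_s.append(hi_s)
        digital.append(dig.astype("<i2"))

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"subject {recording.subject_id}", 80),
            _pad(f"session {recording.session_id}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + nch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(nch), 4),
        ]
    )
    sig = b"".join(_pad(name, 16) for name in recording.channel_names)
    sig += b"".join(_pad("", 80) for _ in range(nch))
    sig += b"".join(_pad("uV", 8) for _ in range(nch))
    sig += b"".join(_pad(s, 8) for s in pmin_s)
    sig += b"".join(_pad(s, 8) for s in pmax_s)
    sig += b"".join(_pad("-32768", 8) for _ in range(nch))
    sig += b"".join(_pad("32767", 8) for _ in range(nch))
    sig += b"".join(_pad("", 80) for _ in range(nch))
    sig += b"".join(_pad(str(fs), 8) for _ in range(nch))
    sig += b"".join(_pad("", 32) for _ in range(nch))

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            for c in range(nch):
                fh.write(digital[c][r * fs : (r + 1) * fs].tobytes())
    return path


def _edf_samples_per_record(path: Path) -> list[int]:
    """Peek the per-signal samples-per-record fields of an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            nch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: unreadable EDF signal count") from exc
        sig = fh.read(256 * nch)
    if len(sig) < 256 * nch:
        raise FormatError(f"{path}: truncated EDF signal headers")
    off = _EDF_SIG_FIELDS * nch
    out = []
    for i in range(nch):
        raw = sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip()
        try:
            out.append(int(raw))
        except ValueError as exc:
            raise FormatError(f"{path}: bad samples-per-record field {raw!r}") from exc
    return out


def read_recording(path: str | Path, format: str = "edf") -> Recording:
    """Read a multichannel recording from an EDF file.

    All signals must share one sampling rate; mixed-rate files are rejected
    rather than silently resampled.
    """
    path = Path(path)
    if format != "edf":
        raise UnsupportedFormatError(f"unsupported format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    spr = _edf_samples_per_record(path)
    if len(set(spr)) > 1:
        raise UnsupportedFormatError(
            f"{path}: signals have differing sampling rates {sorted(set(spr))}"
        )
    import mne  # deferred: mne import is heavy

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data(units="uV")
    return Recording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=path.stem.split("_")[0],
        session_id=path.stem,
    )


# ---------------------------------------------------------------------------
# CHB-MIT-style seizure summaries
# ---------------------------------------------------------------------------


def write_annotations(annotation: StateAnnotation, path: str | Path,
                      file_name: str = "session.edf") -> Path:
    """Emit a CHB-MIT-style plain-text seizure summary for one session.

    Only ictal (seizure) intervals are representable in this format; state
    labels for the remaining time are a labeling-policy matter handled by
    :func:`preictal.pipeline.label_windows`.
    """
    path = Path(path)
    ictal = annotation.intervals_for("ictal")
    lines = [
        f"File Name: {file_name}",
        f"File Duration: {annotation.duration_s:g} seconds",
        f"Number of Seizures in File: {len(ictal)}",
    ]
    for i, (s, e) in enumerate(ictal, start=1):
        lines.append(f"Seizure {i} Start Time: {s:g} seconds")
        lines.append(f"Seizure {i} End Time: {e:g} seconds")
    path.write_text("\n".join(lines) + "\n")
    return path


_SUMMARY_PATTERNS = {
    "duration": re.compile(r"^File Duration:\s*([\d.eE+-]+)\s*seconds\s*$"),
    "count": re.compile(r"^Number of Seizures in File:\s*(\d+)\s*$"),
    "start": re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.eE+-]+)\s*seconds\s*$"),
    "end": re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.eE+-]+)\s*seconds\s*$"),
}


def read_annotations(path: str | Path) -> StateAnnotation:
    """Parse a CHB-MIT-style seizure summary into a :class:`StateAnnotation`.

    The result carries the ictal intervals and onsets listed in the file;
    non-ictal states are not encoded in this format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    duration = None
    n_declared = None
    starts: list[float] = []
    ends: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("File Name:"):
            continue
        for kind, pat in _SUMMARY_PATTERNS.items():
            m = pat.match(line)
            if m:
                val = m.group(1)
                if kind == "duration":
                    duration = float(val)
                elif kind == "count":
                    n_declared = int(val)
                elif kind == "start":
                    starts.append(float(val))
                else:
                    ends.append(float(val))
                break
        else:
            raise FormatError(f"{path}:{lineno}: unrecognized summary line {line!r}")
    if len(starts) != len(ends):
        raise FormatError(f"{path}: {len(starts)} seizure starts but {len(ends)} ends")
    if n_declared is not None and n_declared != len(starts):
        raise FormatError(
            f"{path}: header declares {n_declared} seizures, found {len(starts)}"
        )
    intervals = [(s, e, "ictal") for s, e in zip(starts, ends)]
    ann = StateAnnotation(intervals=intervals, onsets=starts)
    if duration is not None and duration > ann.duration_s:
        ann._file_duration_s = duration  # type: ignore[attr-defined]
    return ann


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(features, path: str | Path) -> Path:
    """Write labeled window features as CSV.

    ``features`` is an iterable of :class:`preictal.pipeline.LabeledWindow`
    (or any object with ``subject_id``, ``session_id``, ``window_index``,
    ``features.as_array()`` and ``label``). Values keep 17 significant digits
    so the round trip is lossless for float64.
    """
    rows = []
    for lw in features:
        vec = lw.features.as_array()
        rows.append(
            {
                "subject": lw.subject_id,
                "session": lw.session_id,
                "window_index": lw.window_index,
                **{col: vec[i] for i, col in enumerate(FEATURE_COLUMNS)},
                "label": lw.label,
            }
        )
    cols = ["subject", "session", "window_index", *FEATURE_COLUMNS, "label"]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["subject", "session", "window_index", *FEATURE_COLUMNS, "label"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    return df
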