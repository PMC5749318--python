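"""Empirical mode decomposition (EMD) and last-IMF denoising.

A signal is sifted into intrinsic mode functions (IMFs): each sift iteration
subtracts the mean of the cubic-spline envelopes through the local maxima and
minima until the IMF conditions hold (extrema and zero-crossing counts differ
by at most one; the mean envelope is near zero), a standard-deviation stopping
criterion fires, or the iteration cap is reached. Decomposition peels IMFs off
until the residue has too few extrema to sift. High-frequency IMFs carry most
of the broadband noise, so the denoised signal is the sum of the last (lowest
frequency) IMFs — four by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline

from .exceptions import ConfigurationError, SiftFailure

#: Mean-envelope tolerance for the IMF test, relative to the signal's peak.
DEFAULT_IMF_TOLERANCE = 0.05
#: Cauchy-type standard-deviation stopping threshold for sifting.
DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_SIFT_ITER = 100
DEFAULT_MAX_IMFS = 12


@dataclass
class IMFSet:
    """Ordered IMFs (highest frequency first) plus the final residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    n_sift_iterations: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs and the residue; equals the input up to roundoff."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    A flat plateau flanked by opposite slopes contributes its midpoint index
    once. Endpoints are never extrema.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ConfigurationError("need at least 3 samples to locate extrema")
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = np.sign(d[nz])
    turn = np.flatnonzero(s[:-1] != s[1:])
    # Plateau [nz[i]+1, nz[i+1]] is flat; its midpoint represents the extremum.
    idx = (nz[turn] + 1 + nz[turn + 1]) // 2
    is_max = s[turn] > 0
    return idx[is_max], idx[~is_max]


def _count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def _count_condition(x: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    maxima, minima = find_extrema(x)
    return abs((maxima.size + minima.size) - _count_zero_crossings(x)) <= 1


def envelope(signal: np.ndarray, extrema_indices: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the given extrema, one value per sample.

    The first and last two extrema are mirrored beyond the signal ends before
    fitting, which suppresses end swings; the interpolant still passes exactly
    through every interior extremum.
    """
    x = np.asarray(signal, dtype=float)
    idx = np.asarray(extrema_indices, dtype=int)
    if idx.size < 2:
        raise SiftFailure("need at least 2 extrema to build an envelope")
    t = idx.astype(float)
    v = x[idx]
    n = x.size
    if idx.size == 2:
        # Too few points for a cubic: straight line between the two extrema.
        return np.interp(np.arange(n, dtype=float), t, v)
    # Mirror up to two extrema about each end of the signal.
    kl = min(2, idx.size)
    left_t = (2 * 0.0 - t[:kl])[::-1]
    left_v = v[:kl][::-1]
    keep = left_t < t[0]
    left_t, left_v = left_t[keep], left_v[keep]
    kr = min(2, idx.size)
    right_t = (2 * (n - 1.0) - t[-kr:])[::-1]
    right_v = v[-kr:][::-1]
    keep = right_t > t[-1]
    right_t, right_v = right_t[keep], right_v[keep]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    spline = CubicSpline(tt, vv, bc_type="natural")
    return spline(np.arange(n, dtype=float))


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    upper = envelope(x, maxima)
    lower = envelope(x, minima)
    return (upper + lower) / 2.0


def is_imf(candidate: np.ndarray, tolerance: float = DEFAULT_IMF_TOLERANCE) -> bool:
    """Check the two IMF conditions.

    1. The number of extrema and of zero crossings differ by at most one.
    2. The mean of the upper and lower envelopes is everywhere below
       ``tolerance`` times the candidate's peak magnitude.
    """
    x = np.asarray(candidate, dtype=float)
    if x.size < 3:
        raise ConfigurationError("need at least 3 samples")
    peak = np.max(np.abs(x))
    if peak == 0:
        return False
    maxima, minima = find_extrema(x)
    n_ext = maxima.size + minima.size
    if abs(n_ext - _count_zero_crossings(x)) > 1:
        return False
    mean_env = _mean_envelope(x)
    if mean_env is None:
        return False
    return bool(np.max(np.abs(mean_env)) <= tolerance * peak)


class SiftResult(NamedTuple):
    imf: np.ndarray
    n_iterations: int
    converged: bool


def sift(
    signal: np.ndarray,
    max_iter: int = DEFAULT_MAX_SIFT_ITER,
    tolerance: float = DEFAULT_IMF_TOLERANCE,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> SiftResult:
    """Extract one IMF by iterated mean-envelope subtraction.

    Stops when the candidate passes :func:`is_imf`, when the normalized
    step-to-step change drops below ``sd_threshold`` (Cauchy criterion), or
    after ``max_iter`` iterations — whichever comes first.
    """
    h = np.asarray(signal, dtype=float).copy()
    maxima, minima = find_extrema(h)
    if maxima.size < 2 or minima.size < 2:
        raise SiftFailure("signal has fewer than 2 maxima or 2 minima")
    converged = False
    it = 0
    while it < max_iter:
        mean_env = _mean_envelope(h)
        if mean_env is None:
            break
        h_new = h - mean_env
        it += 1
        denom = float(np.sum(h * h))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if is_imf(h, tolerance):
            converged = True
            break
        # The SD (Cauchy) criterion alone can stop before the extrema /
        # zero-crossing balance is reached; require both.
        if sd < sd_threshold and _count_condition(h):
            converged = True
            break
    return SiftResult(imf=h, n_iterations=it, converged=converged)


def decompose(
    signal: np.ndarray,
    max_imfs: int = DEFAULT_MAX_IMFS,
    max_iter: int = DEFAULT_MAX_SIFT_ITER,
    tolerance: float = DEFAULT_IMF_TOLERANCE,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
) -> IMFSet:
    """Full EMD: peel IMFs until the residue has too few extrema or the cap.

    Completeness is structural: the residue is updated by exact subtraction,
    so IMFs plus residue reproduce the input to floating-point roundoff.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ConfigurationError("need at least 3 samples")
    residue = x.copy()
    imfset = IMFSet(imfs=[], residue=residue)
    while len(imfset.imfs) < max_imfs:
        maxima, minima = find_extrema(residue)
        if maxima.size < 2 or minima.size < 2:
            break
        try:
            result = sift(residue, max_iter=max_iter, tolerance=tolerance,
                          sd_threshold=sd_threshold)
        except SiftFailure:
            break
        imfset.imfs.append(result.imf)
        imfset.n_sift_iterations.append(result.n_iterations)
        imfset.converged.append(result.converged)
        residue = residue - result.imf
    imfset.residue = residue
    return imfset


def combine_last_imfs(imfset: IMFSet, k: int = 4) -> np.ndarray:
    """Sum of the last ``min(k, n_imfs)`` IMFs — the lowest-frequency modes.

    The residue is never included. This is the denoising step: early IMFs hold
    broadband high-frequency noise, late IMFs the slow rhythms of interest.
    """
    if not imfset.imfs:
        raise ConfigurationError("IMF set is empty")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    kept = imfset.imfs[-min(k, len(imfset.imfs)):]
    return np.sum(kept, axis=0)


def denoise(
    signal: np.ndarray,
    last_k: int = 4,
    max_imfs: int = DEFAULT_MAX_IMFS,
    block_s: float | None = None,
    fs: float | None = None,
    **sift_kwargs,
) -> np.ndarray:
    """Decompose and recombine the last ``last_k`` IMFs.

    By default the whole signal is decomposed at once. With ``block_s`` set
    (requires ``fs``), the signal is processed in consecutive blocks of that
    many seconds and the denoised blocks are concatenated.
    """
    x = np.asarray(signal, dtype=float)
    if block_s is None:
        return combine_last_imfs(decompose(x, max_imfs=max_imfs, **sift_kwargs), last_k)
    if fs is None:
        raise ConfigurationError("block mode requires fs")
    step = int(round(block_s * fs))
    if step < 3:
        raise ConfigurationError("block too short")
    out = np.empty_like(x)
    for start in range(0, x.size, step):
        block = x[start : start + step]
        if block.size < 3:
            out[start : start + step] = block
            continue
        imfset = decompose(block, max_imfs=max_imfs, **sift_kwargs)
        out[start : start + step] = (
            combine_last_imfs(imfset, last_k) if imfset.imfs else block
        )
    return out
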