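"""Spatial filtering: collapse a multichannel recording to one surrogate channel.

Two routes are provided. The averaging filter is the per-sample mean across
channels. The common spatial pattern (CSP) filter is fitted from labeled
two-class data (preictal vs interictal segments): per-class trace-normalized
covariances are averaged, their sum is whitened, and the whitened class-1
covariance is diagonalized; the eigenvector with the largest eigenvalue gives
the projection that maximizes the class-1 / class-2 variance ratio. Because the
whitened class covariances sum to the identity, an eigenvalue lambda for class 1
pairs with 1 - lambda for class 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .exceptions import ConfigurationError, DegenerateSignalError
from .io import Recording


@dataclass
class SurrogateSignal:
    """A single-channel signal derived from a multichannel recording."""

    samples: np.ndarray
    fs: float
    method: str  # "average" or "csp"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()


@dataclass
class CSPFilter:
    """A fitted common spatial pattern filter and all its intermediates.

    Attributes
    ----------
    R1, R2 : ndarray
        Trace-normalized class covariances (class 1 = preictal by convention).
    R : ndarray
        Composite covariance ``R1 + R2``.
    Evec, Eval : ndarray
        Eigenvectors / eigenvalues of ``R`` (descending).
    w : ndarray
        Whitening transform; ``w @ R @ w.T`` is the identity.
    S1, S2 : ndarray
        Whitened class covariances; ``S1 + S2`` is the identity.
    B, D : ndarray
        Eigenvectors of ``S1`` (shared with ``S2``) and its eigenvalues,
        descending; the class-2 eigenvalues are ``1 - D``.
    filter_matrix : ndarray
        Full bank of spatial filters, ``B.T @ w``, rows sorted by descending
        class-1 eigenvalue.
    projection : ndarray
        The single row used for the surrogate channel (first row).
    """

    R1: np.ndarray
    R2: np.ndarray
    R: np.ndarray
    Evec: np.ndarray
    Eval: np.ndarray
    w: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    B: np.ndarray
    D: np.ndarray
    filter_matrix: np.ndarray
    projection: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.filter_matrix.shape[1]

    def to_json(self, path: str | Path) -> Path:
        payload = {
            name: getattr(self, name).tolist()
            for name in ("R1", "R2", "R", "Evec", "Eval", "w", "S1", "S2",
                         "B", "D", "filter_matrix", "projection")
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CSPFilter":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=float) for k, v in payload.items()})


def average_reference(recording: Recording) -> SurrogateSignal:
    """Surrogate channel as the per-sample mean of all channels."""
    if recording.n_channels < 2:
        raise ConfigurationError("averaging needs at least 2 channels")
    return SurrogateSignal(
        samples=recording.samples.mean(axis=0),
        fs=recording.fs,
        method="average",
        provenance=recording.session_id,
    )


def normalized_covariance(X: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance ``(X X^T) / trace(X X^T)`` of one segment."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ConfigurationError("segment must be channels x time with >= 2 samples")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise DegenerateSignalError("zero-energy segment: covariance trace is 0")
    return C / tr


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each eigenvector (column) positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_csp(
    class1_segments: Sequence[np.ndarray],
    class2_segments: Sequence[np.ndarray],
    reg: float = 1e-10,
) -> CSPFilter:
    """Fit a CSP filter from two lists of channels x time segments.

    Class covariances are the averages of per-segment trace-normalized
    covariances. A small ridge (``reg * trace(R)/n`` on the diagonal) is added
    only if the composite covariance is numerically singular.
    """
    if not len(class1_segments) or not len(class2_segments):
        raise ConfigurationError("both classes need at least one segment")
    n_ch = np.asarray(class1_segments[0]).shape[0]
    for seg in list(class1_segments) + list(class2_segments):
        if np.asarray(seg).shape[0] != n_ch:
            raise ConfigurationError("all segments must share the channel count")

    R1 = np.mean([normalized_covariance(s) for s in class1_segments], axis=0)
    R2 = np.mean([normalized_covariance(s) for s in class2_segments], axis=0)
    R = R1 + R2

    Eval, Evec = scipy.linalg.eigh(R)
    if Eval[0] <= Eval[-1] * 1e-12:
        R = R + (reg * np.trace(R) / n_ch) * np.eye(n_ch)
        Eval, Evec = scipy.linalg.eigh(R)
        if Eval[0] <= 0:
            raise DegenerateSignalError("composite covariance is singular")
    order = np.argsort(Eval)[::-1]
    Eval, Evec = Eval[order], _fix_signs(Evec[:, order])

    # Whitening transform: w R w^T = I.
    w = np.diag(1.0 / np.sqrt(Eval)) @ Evec.T
    S1 = w @ R1 @ w.T
    S2 = w @ R2 @ w.T
    S1 = (S1 + S1.T) / 2
    S2 = (S2 + S2.T) / 2

    # S1 and S2 share eigenvectors and their eigenvalues sum to 1, so the
    # ordinary symmetric eigendecomposition of S1 solves the generalized
    # problem; sort descending so the top filter maximizes class-1 variance.
    D, B = scipy.linalg.eigh(S1)
    order = np.argsort(D)[::-1]
    D, B = D[order], _fix_signs(B[:, order])

    filter_matrix = B.T @ w
    return CSPFilter(
        R1=R1, R2=R2, R=R, Evec=Evec, Eval=Eval, w=w, S1=S1, S2=S2,
        B=B, D=D, filter_matrix=filter_matrix, projection=filter_matrix[0].copy(),
    )


def apply_csp(filter: CSPFilter, recording: Recording) -> SurrogateSignal:
    """Project a recording onto the filter's top spatial component."""
    if recording.n_channels != filter.n_channels:
        raise ConfigurationError(
            f"recording has {recording.n_channels} channels, "
            f"filter expects {filter.n_channels}"
        )
    return SurrogateSignal(
        samples=filter.projection @ recording.samples,
        fs=recording.fs,
        method="csp",
        provenance=recording.session_id,
    )
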