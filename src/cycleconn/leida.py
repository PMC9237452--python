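"""Leading Eigenvector Dynamics Analysis (LEiDA).

Each parcel time series is band-pass filtered (0.01–0.1 Hz by default,
zero-phase Butterworth), its instantaneous phase extracted via the Hilbert
transform, and for every functional volume a P×P phase-coherence matrix
cos(θ_i − θ_j) is summarized by its leading eigenvector. The resulting
per-volume unit vectors describe the dominant instantaneous connectivity
pattern; a few volumes at each end are dropped to suppress filter/Hilbert
edge transients.

Eigenvector sign is cosmetic (downstream clustering is sign-invariant); a
fixed convention — the majority of elements negative — is applied so outputs
are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh
from scipy.signal import butter, filtfilt, hilbert

from cycleconn.io_sessions import SessionRecord

DEFAULT_BAND = (0.01, 0.1)  # Hz
DEFAULT_FILTER_ORDER = 2
DEFAULT_EDGE_TRIM = 3  # volumes dropped per end


@dataclass
class PhaseMatrix:
    """T×P instantaneous phases in (−π, π]."""

    theta: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.theta.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.theta.shape[1]


@dataclass
class EigenvectorSet:
    """Per-volume leading eigenvectors (rows, unit norm) with session linkage."""

    vectors: np.ndarray
    session_id: str
    condition: str
    day_index: int
    edge_trim: int
    n_degenerate: int = 0

    @property
    def n_volumes(self) -> int:
        return self.vectors.shape[0]


def bandpass_filter(
    session: SessionRecord,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_FILTER_ORDER,
) -> SessionRecord:
    """Zero-phase Butterworth band-pass per parcel, after demeaning."""
    fs = 1.0 / session.tr
    nyq = fs / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist "
            f"({nyq:.4g} Hz at TR={session.tr}s)"
        )
    b, a = butter(order, [low, high], btype="band", fs=fs)
    demeaned = session.data - session.data.mean(axis=0, keepdims=True)
    filtered = filtfilt(b, a, demeaned, axis=0)
    return replace(session, data=filtered)


def instantaneous_phase(session: SessionRecord) -> PhaseMatrix:
    """Phase of the analytic signal of each (demeaned) parcel series."""
    data = session.data - session.data.mean(axis=0, keepdims=True)
    dead = np.flatnonzero((data == 0).all(axis=0))
    if dead.size:
        raise ValueError(
            f"session {session.session_id!r}: all-zero parcel(s) {dead[:5].tolist()} "
            "have no defined phase"
        )
    analytic = hilbert(data, axis=0)
    return PhaseMatrix(np.angle(analytic))


def phase_coherence_matrix(theta: PhaseMatrix, t: int) -> np.ndarray:
    """cos(θ_i − θ_j) at volume t: symmetric, unit diagonal, values in [−1, 1]."""
    row = theta.theta[t]
    coherence = np.cos(row[:, None] - row[None, :])
    np.fill_diagonal(coherence, 1.0)
    return coherence


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Majority of elements negative; on a tie the first element nonpositive."""
    n_neg = int((v < 0).sum())
    n_pos = int((v > 0).sum())
    if n_neg < n_pos or (n_neg == n_pos and v[0] > 0):
        return -v
    return v


def leading_eigenvector(
    c: np.ndarray, degeneracy_tol: float = 1e-10
) -> tuple[np.ndarray, bool]:
    """Unit eigenvector of the algebraically largest eigenvalue.

    Returns ``(vector, degenerate)`` where ``degenerate`` flags a
    (near-)tied top eigenvalue; in that case any unit vector of the top
    eigenspace is returned under the same sign convention.
    """
    c = np.asarray(c, dtype=float)
    p = c.shape[0]
    if c.shape != (p, p) or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("matrix must be square and symmetric")
    vals, vecs = eigh(c, subset_by_index=(p - 2, p - 1))
    degenerate = bool(vals[1] - vals[0] <= degeneracy_tol * max(1.0, abs(vals[1])))
    v = vecs[:, 1]
    v = v / np.linalg.norm(v)
    return _fix_sign(v), degenerate


def session_eigenvectors(
    session: SessionRecord,
    edge_trim: int = DEFAULT_EDGE_TRIM,
    band: tuple[float, float] | None = DEFAULT_BAND,
    filter_order: int = DEFAULT_FILTER_ORDER,
) -> EigenvectorSet:
    """Full per-session LEiDA: bandpass → phases → per-volume coherence →
    leading eigenvector, dropping ``edge_trim`` volumes at each end.

    ``band=None`` skips filtering (useful when inputs are already filtered).
    """
    if session.n_timepoints - 2 * edge_trim < 1:
        raise ValueError(
            f"edge_trim={edge_trim} leaves no volumes of T={session.n_timepoints}"
        )
    filtered = (
        bandpass_filter(session, band[0], band[1], filter_order)
        if band is not None
        else session
    )
    theta = instantaneous_phase(filtered)
    t_slice = range(edge_trim, session.n_timepoints - edge_trim)
    vectors = np.empty((len(t_slice), session.n_parcels))
    n_degenerate = 0
    for out_row, t in enumerate(t_slice):
        v, degenerate = leading_eigenvector(phase_coherence_matrix(theta, t))
        vectors[out_row] = v
        n_degenerate += degenerate
    if n_degenerate:
        warnings.warn(
            f"session {session.session_id!r}: {n_degenerate} volume(s) with a "
            "degenerate leading eigenvalue",
            RuntimeWarning,
            stacklevel=2,
        )
    return EigenvectorSet(
        vectors=vectors,
        session_id=session.session_id,
        condition=session.condition,
        day_index=session.day_index,
        edge_trim=edge_trim,
        n_degenerate=n_degenerate,
    )
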