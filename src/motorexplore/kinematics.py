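"""From joint-angle time series to per-cycle continuous relative phase.

The processing chain mirrors standard coordination-dynamics practice for
cyclical, gait-like movement: low-pass filter the elbow and knee angle
series, partition the trial into cycles at successive maximal knee
flexions, discard the first and last (push-off / approach) cycles,
amplitude-normalize each retained cycle, and express the arm-leg
coordination of each cycle as the continuous relative phase (CRP)

    crp(t) = wrap(phi_elbow(t) - phi_knee(t))   in (-180, 180] degrees,

with the instantaneous phases phi taken from the Hilbert analytic signal of
the mean-centered, max-abs-normalized angle series of the whole trial
(computing the analytic signal per trial rather than per cycle avoids edge
artifacts at every cycle boundary).  0 deg is in-phase, +/-180 deg
anti-phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "JointAngleTrace",
    "CycleSegment",
    "lowpass_fourier",
    "segment_cycles",
    "continuous_relative_phase",
    "compute_crp",
    "extract_crp_cycles",
    "wrap_degrees",
    "NoCyclesError",
]

L_DEFAULT = 100


class NoCyclesError(ValueError):
    """Raised when a trial yields no usable movement cycles."""


@dataclass
class JointAngleTrace:
    """Elbow and knee angle series for one contiguous trial.

    ``t`` is a uniform time grid in seconds (nominal 100 Hz); angles in
    degrees.  ``meta`` carries learner / session / trial / speed labels.
    """

    t: np.ndarray
    elbow: np.ndarray
    knee: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.elbow = np.asarray(self.elbow, dtype=float)
        self.knee = np.asarray(self.knee, dtype=float)
        if not (self.t.size == self.elbow.size == self.knee.size):
            raise ValueError("t, elbow, knee must have equal length")
        if self.t.size < 3:
            raise ValueError("trace too short")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time vector must be strictly increasing")
        if dt.max() - dt.min() > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform (within 1%)")

    @property
    def fs(self) -> float:
        """Sample rate in Hz."""
        return 1.0 / np.mean(np.diff(self.t))

    def __len__(self) -> int:
        return self.t.size


@dataclass
class CycleSegment:
    """One movement cycle: half-open sample range plus normalized curves."""

    start_idx: int
    end_idx: int
    knee_curve: np.ndarray    # amplitude-normalized to [0, 1], length L
    elbow_curve: np.ndarray

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("end_idx must exceed start_idx")


def wrap_degrees(x) -> np.ndarray:
    """Wrap angles in degrees into the interval (-180, 180]."""
    return -(np.mod(-np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0)


def lowpass_fourier(trace: JointAngleTrace, cutoff: float = 8.0
                    ) -> JointAngleTrace:
    """Low-pass Fourier filter: zero every frequency bin above ``cutoff`` Hz.

    A brick-wall filter in the frequency domain — the passband is untouched
    and the stopband annihilated, so the operation is idempotent.
    """
    fs = trace.fs
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")

    def _filt(x):
        X = np.fft.rfft(x)
        f = np.fft.rfftfreq(x.size, d=1.0 / fs)
        X[f > cutoff] = 0.0
        return np.fft.irfft(X, n=x.size)

    return JointAngleTrace(trace.t, _filt(trace.elbow), _filt(trace.knee),
                           meta=dict(trace.meta))


def _interior_maxima(x: np.ndarray, min_sep: int) -> np.ndarray:
    """Strictly interior local maxima, at least ``min_sep`` samples apart.

    A sample counts as a maximum only if strictly greater than both
    neighbours (plateau ties resolve to the earliest sample of the run).
    When two maxima fall closer than ``min_sep`` the earlier one is kept.
    """
    n = x.size
    peaks = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                peaks.append(i)       # earliest index of the plateau
            i = j + 1
        else:
            i += 1
    kept: list[int] = []
    for p in peaks:
        if not kept or p - kept[-1] >= min_sep:
            kept.append(p)
    return np.asarray(kept, dtype=int)


def _normalize_resample(x: np.ndarray, L: int) -> np.ndarray | None:
    lo, hi = x.min(), x.max()
    if hi - lo <= 1e-12:
        return None
    y = (x - lo) / (hi - lo)
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, L)
    return np.interp(dst, src, y)


def segment_cycles(trace: JointAngleTrace, min_period: float = 0.5,
                   drop_edges: bool = True, L: int = L_DEFAULT
                   ) -> list[CycleSegment]:
    """Partition a trial into movement cycles at maximal knee flexions.

    Cycle boundaries are strictly-interior local maxima of the knee angle
    separated by at least ``min_period`` seconds.  The first and last cycle
    are dropped by default (wall push-off and approach).  Each retained
    cycle is amplitude-normalized per cycle (min -> 0, max -> 1) and
    resampled to ``L`` points; degenerate flat cycles are excluded with a
    warning.
    """
    min_sep = max(1, int(round(min_period * trace.fs)))
    peaks = _interior_maxima(trace.knee, min_sep)
    if peaks.size < 2:
        raise NoCyclesError("no cycles: fewer than two interior knee maxima")
    bounds = list(zip(peaks[:-1], peaks[1:]))
    if drop_edges:
        bounds = bounds[1:-1]
    if not bounds:
        raise NoCyclesError("no cycles remain after dropping edge cycles")
    out: list[CycleSegment] = []
    for a, b in bounds:
        knee = _normalize_resample(trace.knee[a:b + 1], L)
        elbow = _normalize_resample(trace.elbow[a:b + 1], L)
        if knee is None or elbow is None:
            warnings.warn(f"degenerate flat cycle [{a}, {b}) excluded")
            continue
        out.append(CycleSegment(int(a), int(b), knee, elbow))
    if not out:
        raise NoCyclesError("no cycles: all cycles degenerate")
    return out


def _analytic_phase(x: np.ndarray) -> np.ndarray:
    """Unwrapped Hilbert phase (radians) of a centered, normalized signal."""
    x = x - x.mean()
    amp = np.max(np.abs(x))
    if amp <= 1e-12:
        raise ValueError("constant channel: phase undefined")
    return np.unwrap(np.angle(hilbert(x / amp)))


def continuous_relative_phase(elbow: np.ndarray, knee: np.ndarray
                              ) -> np.ndarray:
    """CRP (degrees) between two angle series over their full length."""
    pe = _analytic_phase(np.asarray(elbow, float))
    pk = _analytic_phase(np.asarray(knee, float))
    return wrap_degrees(np.degrees(pe - pk))


def compute_crp(trace: JointAngleTrace, segment: CycleSegment,
                L: int = L_DEFAULT, _crp_full: np.ndarray | None = None
                ) -> np.ndarray:
    """CRP curve for one cycle, resampled to ``L`` points.

    The phases are computed on the whole trial and sliced per cycle.
    """
    crp_full = continuous_relative_phase(trace.elbow, trace.knee) \
        if _crp_full is None else _crp_full
    chunk = crp_full[segment.start_idx:segment.end_idx + 1]
    src = np.linspace(0.0, 1.0, chunk.size)
    dst = np.linspace(0.0, 1.0, L)
    # interpolate the unwrapped curve so +/-180 crossings do not tear
    unwrapped = np.unwrap(np.radians(chunk))
    return wrap_degrees(np.degrees(np.interp(dst, src, unwrapped)))


def extract_crp_cycles(trace: JointAngleTrace, cutoff: float = 8.0,
                       min_period: float = 0.5, drop_edges: bool = True,
                       L: int = L_DEFAULT
                       ) -> tuple[list[CycleSegment], np.ndarray]:
    """Full kinematic chain for one trial.

    Filter -> segment -> per-cycle CRP.  Returns the retained cycle
    segments and an ``(n_cycles, L)`` CRP matrix in chronological order.
    """
    filtered = lowpass_fourier(trace, cutoff=cutoff)
    segments = segment_cycles(filtered, min_period=min_period,
                              drop_edges=drop_edges, L=L)
    crp_full = continuous_relative_phase(filtered.elbow, filtered.knee)
    rows = [compute_crp(filtered, seg, L=L, _crp_full=crp_full)
            for seg in segments]
    return segments, np.vstack(rows)
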