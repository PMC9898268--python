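"""Exponential learning-curve fits to per-session stroke frequency.

Performance in a cyclical task is summarized per session by the mean stroke
frequency f (Hz, the reciprocal of cycle duration); improvement at constant
speed shows up as a decreasing f.  The session means are modelled by the
three-parameter exponential

    f(t) = a * exp(-b * t) + c

where t is the session number (1-based), c the asymptotic performance,
a the initial amplitude above the asymptote (a + c is the level before
practice) and b >= 0 the *learning rate* — larger b, faster approach to the
asymptote.  Fit quality is reported as r^2 and RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SessionPerformance",
    "LearningCurveFit",
    "ExponentialLearningCurve",
    "session_means",
    "fit_exponential",
]


@dataclass
class SessionPerformance:
    """Per-session mean stroke frequency for one learner and condition."""

    t: np.ndarray       # session index, 1-based, strictly increasing
    f: np.ndarray       # mean stroke frequency per session, Hz
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.size != self.f.size:
            raise ValueError("t and f must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("session indices must be strictly increasing")
        if np.any(self.f <= 0):
            raise ValueError("stroke frequencies must be positive")


@dataclass
class LearningCurveFit:
    """Result of an exponential learning-curve fit."""

    a: float
    b: float
    c: float
    r2: float
    rmse: float
    converged: bool = True
    degenerate: bool = False
    meta: dict = field(default_factory=dict)
    perf: "SessionPerformance | None" = None

    def predict(self, t) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(t, float)) + self.c

    def plot(self, ax=None):
        """Plot the session means and the fitted exponential curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.perf is not None:
            ax.plot(self.perf.t, self.perf.f, "o", label="session means")
            grid = np.linspace(self.perf.t[0], self.perf.t[-1], 200)
        else:
            grid = np.linspace(1, 16, 200)
        ax.plot(grid, self.predict(grid), "-",
                label=f"fit (b = {self.b:.3f}/session)")
        ax.set_xlabel("session")
        ax.set_ylabel("stroke frequency (Hz)")
        ax.legend()
        return ax

    def summary(self) -> str:
        flag = " (degenerate)" if self.degenerate else ""
        return "\n".join([
            "Exponential learning curve  f(t) = a·exp(-b·t) + c" + flag,
            f"  a (amplitude):   {self.a: .6g} Hz",
            f"  b (learn. rate): {self.b: .6g} /session",
            f"  c (asymptote):   {self.c: .6g} Hz",
            f"  r^2:             {self.r2: .6g}",
            f"  RMSE:            {self.rmse: .6g} Hz",
            f"  converged:       {self.converged}",
        ])


def session_means(cycle_freqs: dict | list, meta: dict | None = None
                  ) -> SessionPerformance:
    """Arithmetic mean stroke frequency per session.

    ``cycle_freqs`` maps session index -> iterable of per-cycle frequencies
    (Hz), or is a list of such iterables for sessions 1..n.
    """
    if isinstance(cycle_freqs, dict):
        items = sorted(cycle_freqs.items())
    else:
        items = list(enumerate(cycle_freqs, start=1))
    t, f = [], []
    for sess, vals in items:
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            raise ValueError(f"session {sess} has no cycles")
        t.append(sess)
        f.append(vals.mean())
    return SessionPerformance(np.array(t, float), np.array(f, float),
                              meta=dict(meta or {}))


class ExponentialLearningCurve:
    """Nonlinear least-squares model for the exponential learning curve."""

    def __init__(self, perf: SessionPerformance):
        if perf.t.size < 4:
            raise ValueError("need at least 4 sessions to fit 3 parameters")
        self.perf = perf

    @staticmethod
    def _func(t, a, b, c):
        return a * np.exp(-b * t) + c

    def fit(self, n_starts: int = 5, seed: int = 0) -> LearningCurveFit:
        """Fit by multi-start trust-region least squares.

        Starting values: c0 = min(f); a0 and b0 from a log-linear
        regression of f - c0 + eps on t; b0 then jittered by up to +/-50%
        across restarts to avoid the flat local minimum near b = 0.
        Bounds: b in [0, 10], c in [0, max(f)].
        """
        t, f = self.perf.t, self.perf.f
        n = t.size
        spread = f.max() - f.min()
        if spread <= 1e-12:
            return LearningCurveFit(a=0.0, b=0.0, c=float(f.mean()),
                                    r2=1.0, rmse=0.0, converged=True,
                                    degenerate=True,
                                    meta=dict(self.perf.meta),
                                    perf=self.perf)
        c0 = float(f.min())
        eps = 1e-3 * spread
        y = np.log(f - c0 + eps)
        slope, intercept = np.polyfit(t, y, 1)
        b0 = float(np.clip(-slope, 1e-3, 5.0))
        a0 = float(np.exp(intercept))
        rng = np.random.default_rng(seed)
        jitters = np.concatenate([[1.0], 1.0 + rng.uniform(-0.5, 0.5,
                                                           n_starts - 1)])
        lo = [-np.inf, 0.0, 0.0]
        hi = [np.inf, 10.0, float(f.max())]
        best = None
        for j in jitters:
            try:
                popt, _ = curve_fit(self._func, t, f,
                                    p0=[a0, b0 * j, min(c0, hi[2])],
                                    bounds=(lo, hi), maxfev=20000)
            except RuntimeError:
                continue
            sse = float(np.sum((f - self._func(t, *popt)) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)
        if best is None:
            warnings.warn("learning-curve fit did not converge")
            return LearningCurveFit(a=a0, b=b0, c=c0, r2=np.nan,
                                    rmse=np.nan, converged=False,
                                    meta=dict(self.perf.meta),
                                    perf=self.perf)
        (a, b, c), sse = best
        sst = float(np.sum((f - f.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0
        rmse = float(np.sqrt(sse / n))
        return LearningCurveFit(a=float(a), b=float(b), c=float(c),
                                r2=float(r2), rmse=rmse, converged=True,
                                meta=dict(self.perf.meta), perf=self.perf)


def fit_exponential(perf: SessionPerformance | tuple, **kwargs
                    ) -> LearningCurveFit:
    """Convenience: fit the exponential model to session means."""
    if not isinstance(perf, SessionPerformance):
        t, f = perf
        perf = SessionPerformance(np.asarray(t, float), np.asarray(f, float))
    return ExponentialLearningCurve(perf).fit(**kwargs)
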