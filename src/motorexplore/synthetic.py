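"""Seeded synthetic learners with known exploration strategies.

The generator emulates the structure of a two-month breaststroke learning
protocol: several learners, two speed conditions, 16 sessions of 5 trials,
each trial a handful of movement cycles.  Every learner follows a *known*
drifting transition structure over coordination patterns, so each
downstream stage (cycle extraction, clustering, drift modelling, the
exploration statistic, learning-curve fits) can be checked against ground
truth.

Strategy presets follow the classical search-strategy taxonomy:

``blind``
    near-uniform transition rows at every support — undirected random
    search with no drift.
``linear``
    a straight drift from a start-concentrated matrix toward a
    target-concentrated matrix — gradual, history-dependent search.
``anchored_local``
    interior supports concentrate mass on successive adjacent anchor
    patterns — temporary anchor points visited on the way to the target.
``hybrid_nonlocal``
    interior anchors jump to non-adjacent patterns — discontinuous search.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dmm import PatternLabelSequence, simulate_labels
from .kinematics import JointAngleTrace, L_DEFAULT

__all__ = [
    "LearnerScenario",
    "SyntheticTruth",
    "TrialRecord",
    "LearnerDataset",
    "default_templates",
    "make_strategy_supports",
    "gen_angle_traces",
    "gen_performance_series",
    "generate_learner",
    "generate_cohort",
]

STRATEGIES = ("blind", "linear", "anchored_local", "hybrid_nonlocal")


# ---------------------------------------------------------------------------
# templates and supports


def default_templates(m: int, L: int = L_DEFAULT) -> np.ndarray:
    """Default CRP template per pattern: anti-phase anchored excursions.

    Every template starts and ends a cycle in anti-phase (-180 deg, the
    coordination at maximal knee flexion) and makes a smooth excursion
    toward in-phase at mid-cycle; templates differ in excursion depth,
    evenly spaced between 30 and 90 deg.  The deepest excursion is the
    most expert-like shape (anti-phase -> toward in-phase -> anti-phase).

    Sharing the boundary value keeps the synthesized elbow phase continuous
    across cycle boundaries, so one cycle's coordination does not bleed
    into its neighbours; capping the excursion depth keeps the synthesized
    elbow phase monotone, so its analytic-signal phase is well defined.
    """
    if m < 2:
        raise ValueError("need at least two patterns")
    u = np.linspace(0.0, 1.0, L)
    amps = np.linspace(30.0, 90.0, m)
    return np.stack([-180.0 + a * np.sin(np.pi * u) ** 2 for a in amps])


def _concentrated(m: int, col: int, mass: float) -> np.ndarray:
    """All rows place ``mass`` on 1-based column ``col``, the rest uniform."""
    off = (1.0 - mass) / (m - 1)
    P = np.full((m, m), off)
    P[:, col - 1] = mass
    return P


def make_strategy_supports(strategy: str, m: int, degree: int,
                           params: dict | None = None) -> list[np.ndarray]:
    """Row-stochastic support matrices realizing a search-strategy preset.

    Returns ``degree + 1`` matrices of shape ``(m, m)``.  ``params`` may
    override ``anchor_mass`` (default 0.85, the concentration placed on an
    anchor pattern).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if m < 2:
        raise ValueError("m must be >= 2")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    mass = float((params or {}).get("anchor_mass", 0.85))

    if strategy == "blind":
        return [np.full((m, m), 1.0 / m) for _ in range(degree + 1)]

    if strategy == "linear":
        if degree < 1:
            raise ValueError("linear strategy requires degree >= 1")
        P_start = _concentrated(m, 1, mass)
        P_end = _concentrated(m, m, mass)
        return [
            (1.0 - i / degree) * P_start + (i / degree) * P_end
            for i in range(degree + 1)
        ]

    if degree < 2:
        raise ValueError(f"{strategy} requires degree >= 2 (interior supports)")

    if strategy == "anchored_local":
        anchors = [int(round(1 + (m - 1) * i / degree)) for i in range(degree + 1)]
    else:  # hybrid_nonlocal: half-rotation jumps, non-adjacent for m >= 4
        if m < 4:
            raise ValueError("hybrid_nonlocal requires m >= 4")
        anchors = [1]
        jump = (m + 1) // 2
        for _ in range(degree - 1):
            anchors.append((anchors[-1] - 1 + jump) % m + 1)
        anchors.append(m)
    return [_concentrated(m, a, mass) for a in anchors]


# ---------------------------------------------------------------------------
# scenario


@dataclass
class LearnerScenario:
    """One synthetic learner in one speed condition."""

    strategy: str
    m: int = 11
    drift_degree: int = 3
    cycles_per_session: list[int] = field(default_factory=list)
    cycle_period: float = 1.2          # s, base cycle duration
    crp_noise_sd: float = 5.0          # deg, white phase-offset jitter
    perf_params: tuple = (0.35, 0.20, 0.50, 0.02)   # a (Hz), b (1/session), c (Hz), sigma (Hz)
    seed: int = 0
    trials_per_session: int = 5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.crp_noise_sd < 0 or self.perf_params[3] < 0:
            raise ValueError("noise levels must be non-negative")
        if not self.cycles_per_session:
            self.cycles_per_session = self._draw_cycles()
        lo = 3 * self.trials_per_session
        hi = 17 * self.trials_per_session
        for c in self.cycles_per_session:
            if not lo <= c <= hi:
                raise ValueError(
                    f"cycles per session must lie in [{lo}, {hi}]")

    def _draw_cycles(self, n_sessions: int = 16) -> list[int]:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 101]))
        per_trial = rng.integers(3, 18, size=(n_sessions, self.trials_per_session))
        return per_trial.sum(axis=1).tolist()

    @property
    def n_sessions(self) -> int:
        return len(self.cycles_per_session)

    @property
    def n_cycles(self) -> int:
        return int(sum(self.cycles_per_session))


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated learner."""

    true_labels: PatternLabelSequence
    true_supports: list[np.ndarray]
    true_perf: np.ndarray              # per-session stroke frequency, Hz
    templates: np.ndarray              # (m, L) CRP template curves, deg
    cycle_bounds: list | None = None   # per-trial exact boundaries (samples)

    def to_json(self) -> str:
        return json.dumps({
            "schema": "motorexplore.truth/1",
            "labels": self.true_labels.labels.tolist(),
            "m": self.true_labels.m,
            "supports": [P.tolist() for P in self.true_supports],
            "perf": self.true_perf.tolist(),
            "templates": self.templates.tolist(),
        })


@dataclass
class TrialRecord:
    """One generated trial: its angle trace and interior-cycle labels."""

    trace: JointAngleTrace
    session: int
    trial: int
    labels: np.ndarray     # labels of the interior (retained) cycles


@dataclass
class LearnerDataset:
    scenario: LearnerScenario
    trials: list[TrialRecord]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# generators


def gen_performance_series(a: float, b: float, c: float, sigma: float,
                           n_sessions: int, seed=None) -> np.ndarray:
    """Per-session stroke frequency a*exp(-b*t) + c + N(0, sigma^2),
    t = 1..n_sessions."""
    if n_sessions < 2:
        raise ValueError("need at least two sessions")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    t = np.arange(1, n_sessions + 1, dtype=float)
    f = a * np.exp(-b * t) + c
    if sigma > 0:
        f = f + np.random.default_rng(seed).normal(0.0, sigma, size=n_sessions)
    return f


def gen_angle_traces(labels, templates: np.ndarray, cycle_period: float,
                     noise_sd: float = 0.0, seed=None, fs: float = 100.0,
                     meta: dict | None = None
                     ) -> tuple[JointAngleTrace, np.ndarray]:
    """Synthesize a 100 Hz elbow/knee trace realizing a labelled cycle train.

    The knee oscillates at fixed period with maxima at cycle boundaries;
    the elbow is the same oscillation phase-shifted by the CRP template of
    each cycle's pattern (plus i.i.d. Gaussian noise on the phase offset).
    Half a period of margin is prepended and appended so that every cycle
    boundary is a strictly interior knee maximum.

    Returns the trace and the exact cycle-boundary sample indices
    (``n_cycles + 1`` values).
    """
    labels = np.asarray(labels, dtype=np.int64)
    templates = np.asarray(templates, dtype=float)
    if labels.min() < 1 or labels.max() > templates.shape[0]:
        raise ValueError("missing template for a label")
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    n_cyc = labels.size
    P = cycle_period
    margin = int(round(0.5 * P * fs))
    n_samp = int(round(n_cyc * P * fs)) + 2 * margin
    t = (np.arange(n_samp) - margin) / fs           # t = 0 at first boundary

    pos = t / P                                     # position in cycle units
    cyc = np.clip(np.floor(pos).astype(int), 0, n_cyc - 1)
    frac = pos - np.floor(pos)
    Lt = templates.shape[1]
    tpl_grid = np.linspace(0.0, 1.0, Lt)
    delta = np.empty(n_samp)
    for k in np.unique(cyc):
        mask = cyc == k
        delta[mask] = np.interp(frac[mask], tpl_grid, templates[labels[k] - 1])
    if noise_sd > 0:
        delta = delta + np.random.default_rng(seed).normal(0.0, noise_sd,
                                                           n_samp)

    knee = np.cos(2 * np.pi * t / P)
    elbow = np.cos(2 * np.pi * t / P + np.radians(delta))
    bounds = margin + np.round(np.arange(n_cyc + 1) * P * fs).astype(int)
    trace = JointAngleTrace(np.arange(n_samp) / fs, elbow, knee,
                            meta=dict(meta or {}))
    return trace, bounds


def generate_learner(scenario: LearnerScenario) -> LearnerDataset:
    """Generate one learner's full protocol with ground truth.

    Every trial carries two sacrificial padding cycles (repeats of its
    first and last pattern) so that after the downstream edge-cycle drop
    the recovered chronological label sequence matches ``truth.true_labels``
    exactly.  The session cycle period follows the learner's performance
    curve (period = 1 / stroke frequency), so session-mean frequencies
    recover the generated learning curve.
    """
    sc = scenario
    ss = np.random.SeedSequence([sc.seed, 7])
    s_labels, s_perf, s_trials = ss.spawn(3)

    supports = make_strategy_supports(
        sc.strategy, sc.m,
        max(sc.drift_degree, 1) if sc.strategy == "linear" else sc.drift_degree)
    n_cycles = sc.n_cycles
    rng_init = np.random.default_rng(s_labels)
    initial = 1 if sc.strategy != "blind" else int(rng_init.integers(1, sc.m + 1))
    seq = simulate_labels(supports, n_cycles - 1, initial,
                          seed=np.random.default_rng(s_labels))

    a, b, c, sigma = sc.perf_params
    perf = gen_performance_series(a, b, c, sigma, sc.n_sessions,
                                  seed=np.random.default_rng(s_perf))
    perf = np.maximum(perf, 0.1)        # keep periods physical

    templates = default_templates(sc.m)
    trial_rngs = s_trials.spawn(sc.n_sessions * sc.trials_per_session)
    rng_split = np.random.default_rng(np.random.SeedSequence([sc.seed, 13]))

    trials: list[TrialRecord] = []
    cursor = 0
    k = 0
    for sess in range(sc.n_sessions):
        counts = _split_session(sc.cycles_per_session[sess],
                                sc.trials_per_session, rng_split)
        period = 1.0 / perf[sess]
        for tr, cnt in enumerate(counts):
            lab = seq.labels[cursor:cursor + cnt]
            cursor += cnt
            padded = np.concatenate([[lab[0]], lab, [lab[-1]]])
            trace, _ = gen_angle_traces(
                padded, templates, period, noise_sd=sc.crp_noise_sd,
                seed=np.random.default_rng(trial_rngs[k]), fs=100.0,
                meta={"learner": sc.meta.get("learner", 0),
                      "speed": sc.meta.get("speed", "low"),
                      "session": sess + 1, "trial": tr + 1})
            trials.append(TrialRecord(trace, sess + 1, tr + 1, lab))
            k += 1
    truth = SyntheticTruth(seq, [np.asarray(P) for P in supports],
                           perf, templates)
    return LearnerDataset(sc, trials, truth)


def _split_session(total: int, n_trials: int, rng) -> list[int]:
    """Split a session's cycle count into per-trial counts in [3, 17]."""
    counts = [3] * n_trials
    remaining = total - 3 * n_trials
    while remaining > 0:
        order = rng.permutation(n_trials)
        for i in order:
            if remaining == 0:
                break
            if counts[i] < 17:
                counts[i] += 1
                remaining -= 1
    return counts


def generate_cohort(n_learners: int = 7, conditions=("low", "high"),
                    strategies=None, m: int = 11, seed: int = 0,
                    **scenario_kwargs) -> list[LearnerDataset]:
    """Generate a cohort of learners across speed conditions.

    Strategies cycle through the presets unless given explicitly (one per
    learner).  The high-speed condition uses a higher-frequency performance
    curve, mirroring the harder task constraint.
    """
    if strategies is None:
        pool = [s for s in STRATEGIES]
        strategies = [pool[i % len(pool)] for i in range(n_learners)]
    out: list[LearnerDataset] = []
    for i in range(n_learners):
        for j, cond in enumerate(conditions):
            perf = (0.35, 0.20, 0.50, 0.02) if cond == "low" \
                else (0.30, 0.28, 0.65, 0.02)
            kwargs = dict(perf_params=perf)
            kwargs.update(scenario_kwargs)
            sc = LearnerScenario(
                strategy=strategies[i], m=m,
                seed=int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0]
                         % (2**31)),
                meta={"learner": i + 1, "speed": cond},
                **kwargs)
            out.append(generate_learner(sc))
    return out
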