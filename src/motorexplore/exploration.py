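"""Quantity of exploration: distance between two drift models of learning.

A learner whose transition probabilities toward each coordination pattern
evolve linearly is not exploring: patterns simply appear or disappear at a
constant rate.  Fluctuations around that linear trend — a pattern anchored
for a while and then abandoned — are the signature of exploration.  The
statistic computed here is, per pattern, the average distance between the
degree-1 (linear drift) and degree-3 (flexible drift) descriptions of the
same label sequence, expressed in percent.

Two readings of "distance between the two models" are implemented:

``appearance`` (default)
    mean absolute difference of the two models' simulated probabilities of
    appearance of the pattern along the sequence.
``column``
    root-mean-square difference of the transition probabilities *toward*
    the pattern (its column in the drifting transition matrix), averaged
    along the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmm import DriftingMarkovResults, _as_sequence

__all__ = ["ExplorationProfile", "exploration_quantity", "exploration_summary"]


@dataclass
class ExplorationProfile:
    """Per-pattern exploration quantities for one learner and condition."""

    Q: np.ndarray                 # percent, one value per pattern 1..m
    visited: int                  # number of distinct patterns in the data
    visited_mask: np.ndarray      # which patterns occur in the sequence
    sd_across_patterns: float     # sample SD of Q over all m patterns, %
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.Q.size


def exploration_quantity(res_d1: DriftingMarkovResults,
                         res_d3: DriftingMarkovResults,
                         p0=None, mode: str = "appearance") -> np.ndarray:
    """Per-pattern exploration quantity (%) between two drift models.

    Parameters
    ----------
    res_d1, res_d3 : DriftingMarkovResults
        Two models of the same sequence (same alphabet size and length);
        conventionally the linear (degree-1) and flexible (degree-3) fits.
    p0 : array-like, optional
        Initial distribution for the appearance simulation; defaults to the
        indicator of the first observed label.
    mode : {"appearance", "column"}

    Returns
    -------
    ndarray of shape (m,) with values in [0, 100].
    """
    if res_d1.m != res_d3.m:
        raise ValueError("models disagree on alphabet size m")
    if res_d1.n != res_d3.n:
        raise ValueError("models disagree on sequence length n")
    m, n = res_d1.m, res_d1.n
    if mode == "appearance":
        if p0 is None and res_d1.model is not None:
            p0 = np.zeros(m)
            p0[res_d1.model.data.labels[0] - 1] = 1.0
        A1 = res_d1.appearance_probabilities(p0)
        A3 = res_d3.appearance_probabilities(p0)
        return 100.0 * np.abs(A3 - A1).mean(axis=0)
    if mode == "column":
        ts = np.arange(1, n + 1)
        P1 = res_d1.transition_at(ts)
        P3 = res_d3.transition_at(ts)
        persq = ((P3 - P1) ** 2).mean(axis=1)      # (n, m): mean over origin u
        return 100.0 * np.sqrt(persq).mean(axis=0)
    raise ValueError("mode must be 'appearance' or 'column'")


def exploration_summary(Q: np.ndarray, seq, meta: dict | None = None
                        ) -> ExplorationProfile:
    """Summarize per-pattern exploration for one learner and condition.

    ``visited`` counts the distinct patterns actually present in the label
    sequence; patterns never visited keep their computed Q but are flagged
    through ``visited_mask`` rather than imputed to zero.  The dispersion is
    the sample standard deviation (n-1 denominator) of Q over all patterns.
    """
    Q = np.asarray(Q, dtype=float)
    seq = _as_sequence(seq, m=Q.size)
    if seq.m != Q.size:
        raise ValueError("Q length must equal the alphabet size")
    mask = seq.visited()
    sd = float(np.std(Q, ddof=1)) if Q.size > 1 else 0.0
    return ExplorationProfile(Q=Q, visited=int(mask.sum()), visited_mask=mask,
                              sd_across_patterns=sd, meta=dict(meta or {}))
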