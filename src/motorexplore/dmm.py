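"""Drifting Markov models for categorical behavioural sequences.

An order-1 Markov chain whose transition matrix drifts smoothly along the
sequence: the matrix at relative position ``s = t/n`` is the Lagrange
interpolation of ``d + 1`` row-stochastic *support matrices* anchored at the
equispaced points ``i/d``.  Degree 0 is the classical homogeneous chain;
degree 1 is a linear drift between a start and an end matrix; degree 3
allows patterns to rise and fall again along the sequence.

The model is estimated by maximum likelihood over the support matrices,
each row constrained to the probability simplex.  Because the interpolated
matrix can leave ``[0, 1]`` between support points when the degree exceeds 1,
evaluated transition probabilities are clipped and row-renormalized, and
violations on the data grid are penalized during fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "PatternLabelSequence",
    "DriftingMarkov",
    "DriftingMarkovResults",
    "ModelScore",
    "fit_dmm",
    "simulate_labels",
    "lagrange_weights",
]


# ---------------------------------------------------------------------------
# label sequences


@dataclass
class PatternLabelSequence:
    """A chronological sequence of categorical pattern labels.

    Labels live on the alphabet ``{1, ..., m}``.  ``n`` is the number of
    *transitions*, i.e. ``len(labels) - 1``.
    """

    labels: np.ndarray
    m: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 2:
            raise ValueError("need a 1-d sequence with at least one transition")
        if self.m < 2:
            raise ValueError("alphabet size m must be >= 2")
        if self.labels.min() < 1 or self.labels.max() > self.m:
            raise ValueError("labels must lie in 1..m")

    @property
    def n(self) -> int:
        return self.labels.size - 1

    def __len__(self) -> int:
        return self.labels.size

    @classmethod
    def from_string(cls, s: str, alphabet: str | None = None) -> "PatternLabelSequence":
        """Build from a plain character string, e.g. a nucleotide sequence.

        The alphabet defaults to the sorted set of characters present, so
        ``from_string("acgt...")`` models the four nucleotides.
        """
        if alphabet is None:
            alphabet = "".join(sorted(set(s)))
        lut = {c: i + 1 for i, c in enumerate(alphabet)}
        try:
            labels = np.array([lut[c] for c in s], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise ValueError(f"character {exc} not in alphabet {alphabet!r}") from exc
        seq = cls(labels, m=len(alphabet))
        seq.meta["alphabet"] = alphabet
        return seq

    def visited(self) -> np.ndarray:
        """Boolean mask over 1..m of patterns that occur in the sequence."""
        out = np.zeros(self.m, dtype=bool)
        out[np.unique(self.labels) - 1] = True
        return out


def _as_sequence(seq, m=None) -> PatternLabelSequence:
    if isinstance(seq, PatternLabelSequence):
        return seq
    arr = np.asarray(seq, dtype=np.int64)
    if m is None:
        m = int(arr.max())
    return PatternLabelSequence(arr, m=m)


# ---------------------------------------------------------------------------
# Lagrange drift basis


def lagrange_weights(s, degree: int) -> np.ndarray:
    """Lagrange basis weights at relative positions ``s`` for nodes ``i/d``.

    Returns an array of shape ``(len(s), degree + 1)`` whose rows sum to 1.
    Degree 0 returns a single column of ones.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if degree == 0:
        return np.ones((s.size, 1))
    nodes = np.arange(degree + 1) / degree
    W = np.ones((s.size, degree + 1))
    for i in range(degree + 1):
        for j in range(degree + 1):
            if j != i:
                W[:, i] *= (s - nodes[j]) / (nodes[i] - nodes[j])
    return W


def _interp_supports(supports: np.ndarray, s) -> np.ndarray:
    """Interpolated (unclipped) transition matrices at positions ``s``."""
    W = lagrange_weights(s, supports.shape[0] - 1)
    return np.einsum("ti,iuv->tuv", W, supports)


def _clip_renorm(P: np.ndarray) -> np.ndarray:
    """Clip entries to [0, 1] and renormalize rows; safe for any row."""
    Q = np.clip(P, 0.0, 1.0)
    rows = Q.sum(axis=-1, keepdims=True)
    # a row that sums to 1 before clipping cannot clip to all-zero, but be safe
    bad = rows <= 0
    if np.any(bad):
        Q = np.where(bad, 1.0, Q)
        rows = Q.sum(axis=-1, keepdims=True)
    return Q / rows


# ---------------------------------------------------------------------------
# scores


@dataclass
class ModelScore:
    """Log-likelihood with AIC/BIC on the smaller-is-better convention."""

    loglik: float
    npar: int
    n: int
    zero_transitions: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.npar

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.npar * np.log(self.n)


# ---------------------------------------------------------------------------
# model


class DriftingMarkov:
    """Order-1 drifting Markov model of a pattern label sequence.

    Parameters
    ----------
    endog : sequence of int or PatternLabelSequence
        Chronological labels on ``1..m``.
    degree : int
        Polynomial drift degree ``d``; ``d + 1`` support matrices.
    m : int, optional
        Alphabet size; defaults to the largest label seen.  Pass explicitly
        when some patterns are never visited so that models remain
        comparable across sequences.
    alpha : float
        Laplace pseudo-count used for the homogeneous initializer (and for
        otherwise-unobserved rows), so likelihoods stay finite for patterns
        that never occur.
    floor : float
        Lower floor applied to evaluated transition probabilities.
    """

    def __init__(self, endog, degree: int = 1, m: int | None = None,
                 alpha: float = 0.5, floor: float = 1e-12):
        self.data = _as_sequence(endog, m=m)
        if degree < 0:
            raise ValueError("degree must be >= 0")
        if self.data.n < degree + 1:
            raise ValueError(
                f"sequence with {self.data.n} transitions too short for degree {degree}"
            )
        self.degree = int(degree)
        self.m = self.data.m
        self.alpha = float(alpha)
        self.floor = float(floor)
        n = self.data.n
        self._s = np.arange(1, n + 1) / n
        self._W = lagrange_weights(self._s, self.degree)
        self._u = self.data.labels[:-1] - 1
        self._v = self.data.labels[1:] - 1

    # -- empirical estimates -------------------------------------------------

    def transition_counts(self) -> np.ndarray:
        C = np.zeros((self.m, self.m))
        np.add.at(C, (self._u, self._v), 1.0)
        return C

    def empirical_mle(self, alpha: float = 0.0) -> np.ndarray:
        """Count-based homogeneous MLE; unvisited rows fall back to uniform.

        With ``alpha > 0`` every cell gets a pseudo-count (Laplace
        smoothing); with ``alpha = 0`` the estimate is the exact count ratio.
        """
        C = self.transition_counts() + alpha
        rows = C.sum(axis=1, keepdims=True)
        P = np.where(rows > 0, C / np.where(rows == 0, 1.0, rows),
                     np.full((self.m, self.m), 1.0 / self.m))
        return P

    # -- likelihood machinery ------------------------------------------------

    def _objective(self, z: np.ndarray, penalty: float):
        """Penalized negative log-likelihood and gradient in logit space."""
        d1, m = self.degree + 1, self.m
        Z = z.reshape(d1, m, m)
        Z = Z - Z.max(axis=2, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=2, keepdims=True)

        Pi = np.einsum("ti,iuv->tuv", self._W, P)           # (n, m, m)
        p_obs = Pi[np.arange(self._u.size), self._u, self._v]
        p_safe = np.maximum(p_obs, self.floor)
        ll = np.log(p_safe).sum()

        G = np.zeros_like(P)                                 # d ll / dP
        live = p_obs > self.floor
        w = np.zeros_like(p_obs)
        w[live] = 1.0 / p_obs[live]
        # accumulate w_t * W[t, i] into G[i, u_t, v_t]
        for i in range(d1):
            np.add.at(G[i], (self._u, self._v), w * self._W[:, i])

        pen = 0.0
        if self.degree >= 2 and penalty > 0:
            neg = np.minimum(Pi, 0.0)
            over = np.maximum(Pi - 1.0, 0.0)
            pen = penalty * (np.sum(neg**2) + np.sum(over**2))
            Gpen = 2.0 * penalty * (neg + over)              # (n, m, m)
            G -= np.einsum("ti,tuv->iuv", self._W, Gpen)

        f = -(ll - pen)
        # chain rule through row-softmax
        inner = np.einsum("iuv,iuv->iu", G, P)
        dZ = P * (G - inner[:, :, None])
        return f, -dZ.ravel()

    def loglike(self, supports: np.ndarray) -> ModelScore:
        """Exact log-likelihood of the data under given supports.

        Probabilities are evaluated with the clip-and-renormalize
        convention and floored at ``self.floor``; if a floor of 0 exposes an
        exactly-zero observed transition the log-likelihood is ``-inf`` and
        the offending ``(t, u, v)`` triples are listed in the score.
        """
        supports = np.asarray(supports, dtype=float)
        Pi = _clip_renorm(_interp_supports(supports, self._s))
        p = Pi[np.arange(self._u.size), self._u, self._v]
        zero = p <= self.floor
        npar = (self.degree + 1) * self.m * (self.m - 1)
        if self.floor > 0:
            ll = float(np.log(np.maximum(p, self.floor)).sum())
            offenders = []
        else:
            offenders = [
                (int(t + 1), int(self._u[t] + 1), int(self._v[t] + 1))
                for t in np.nonzero(zero)[0]
            ]
            ll = -np.inf if offenders else float(np.log(p).sum())
        return ModelScore(loglik=ll, npar=npar, n=self.data.n,
                          zero_transitions=offenders)

    # -- fitting -------------------------------------------------------------

    def fit(self, penalty: float = 1e5, maxiter: int = 2000,
            tol: float = 1e-8, method: str = "ml") -> "DriftingMarkovResults":
        """Estimate the support matrices.

        ``method="ml"`` (default) maximizes the drifting-chain likelihood by
        L-BFGS on row-softmax parameters, initialized at the smoothed
        homogeneous estimate (and, for degree >= 2, additionally at the
        embedded degree-1 solution, which guarantees the nested-likelihood
        ordering).  ``method="ls"`` returns the least-squares style moment
        fit: supports solving the weighted-count normal equations projected
        to the simplex — kept as a cheap cross-check.
        """
        if method not in ("ml", "ls"):
            raise ValueError("method must be 'ml' or 'ls'")
        P0 = self.empirical_mle(alpha=self.alpha)
        if self.degree == 0:
            # exact count-based MLE (unsmoothed): closed form optimum
            supports = self.empirical_mle(alpha=0.0)[None, :, :]
            return self._make_results(supports, converged=True, nit=0)
        if method == "ls":
            supports = self._fit_ls(P0)
            return self._make_results(supports, converged=True, nit=0)

        inits = [np.repeat(P0[None, :, :], self.degree + 1, axis=0)]
        if self.degree >= 2:
            sub = DriftingMarkov(self.data, degree=1, m=self.m,
                                 alpha=self.alpha, floor=self.floor)
            res1 = sub.fit(penalty=penalty, maxiter=maxiter, tol=tol)
            nodes = np.arange(self.degree + 1) / self.degree
            embedded = _clip_renorm(_interp_supports(res1.supports, nodes))
            inits.append(embedded)

        best = None
        for P_init in inits:
            z0 = np.log(np.maximum(P_init, 1e-10)).ravel()
            out = optimize.minimize(
                self._objective, z0, args=(penalty,), jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
            )
            Z = out.x.reshape(self.degree + 1, self.m, self.m)
            E = np.exp(Z - Z.max(axis=2, keepdims=True))
            supports = E / E.sum(axis=2, keepdims=True)
            for cand, conv, nit in ((supports, bool(out.success), int(out.nit)),
                                    (P_init, True, 0)):
                ll = self.loglike(cand).loglik
                if best is None or ll > best[1]:
                    best = (cand, ll, conv, nit)
        supports, _, conv, nit = best
        return self._make_results(supports, converged=conv, nit=nit)

    def _fit_ls(self, P0: np.ndarray) -> np.ndarray:
        """Row-wise weighted least squares on transition indicators.

        For each origin state u, regress the one-hot next-state indicator on
        the Lagrange weights of the transition positions, then project each
        support row back to the simplex.
        """
        d1, m = self.degree + 1, self.m
        supports = np.repeat(P0[None, :, :], d1, axis=0)
        for u in range(m):
            idx = np.nonzero(self._u == u)[0]
            if idx.size < d1:
                continue
            W = self._W[idx]                     # (k, d1)
            Y = np.zeros((idx.size, m))
            Y[np.arange(idx.size), self._v[idx]] = 1.0
            B, *_ = np.linalg.lstsq(W, Y, rcond=None)   # (d1, m)
            B = np.maximum(B, self.floor)
            supports[:, u, :] = B / B.sum(axis=1, keepdims=True)
        return supports

    def _make_results(self, supports, converged, nit) -> "DriftingMarkovResults":
        score = self.loglike(supports)
        return DriftingMarkovResults(self, np.asarray(supports, float),
                                     score, converged, nit)


class DriftingMarkovResults:
    """Fitted drifting Markov model: supports, scores, simulation."""

    def __init__(self, model: DriftingMarkov, supports: np.ndarray,
                 score: ModelScore, converged: bool = True, nit: int = 0):
        self.model = model
        self.supports = supports
        self.score = score
        self.converged = converged
        self.nit = nit

    # construction without data, e.g. a ground-truth generator model
    @classmethod
    def from_supports(cls, supports, n: int, floor: float = 1e-12
                      ) -> "DriftingMarkovResults":
        supports = np.asarray(supports, dtype=float)
        if supports.ndim != 3 or supports.shape[1] != supports.shape[2]:
            raise ValueError("supports must be (d+1, m, m)")
        m = supports.shape[1]
        if not np.allclose(supports.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("support rows must sum to 1")
        obj = cls.__new__(cls)
        obj.model = None
        obj.supports = supports
        obj.score = None
        obj.converged = True
        obj.nit = 0
        obj._m = m
        obj._n = int(n)
        obj._floor = floor
        return obj

    @property
    def m(self) -> int:
        return self.model.m if self.model is not None else self._m

    @property
    def n(self) -> int:
        return self.model.data.n if self.model is not None else self._n

    @property
    def degree(self) -> int:
        return self.supports.shape[0] - 1

    @property
    def loglik(self) -> float:
        return self.score.loglik

    @property
    def aic(self) -> float:
        return self.score.aic

    @property
    def bic(self) -> float:
        return self.score.bic

    def transition_at(self, t) -> np.ndarray:
        """Transition matrix at sequence position ``t`` (0..n), clipped and
        row-renormalized."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.n):
            raise ValueError(f"t must lie in [0, {self.n}]")
        scalar = t.ndim == 0
        Pi = _clip_renorm(_interp_supports(self.supports, np.atleast_1d(t) / self.n))
        return Pi[0] if scalar else Pi

    def appearance_probabilities(self, p0=None) -> np.ndarray:
        """Marginal probability of each pattern at every position 0..n.

        ``p0`` is the initial distribution; it defaults to the indicator of
        the first observed label (uniform for data-free models).
        """
        if p0 is None:
            if self.model is not None:
                p0 = np.zeros(self.m)
                p0[self.model.data.labels[0] - 1] = 1.0
            else:
                p0 = np.full(self.m, 1.0 / self.m)
        p0 = np.asarray(p0, dtype=float)
        if p0.shape != (self.m,) or not np.isclose(p0.sum(), 1.0, atol=1e-8) \
                or np.any(p0 < 0):
            raise ValueError("p0 must be a distribution over the m patterns")
        out = np.empty((self.n + 1, self.m))
        out[0] = p0 / p0.sum()
        Pi = _clip_renorm(_interp_supports(self.supports,
                                           np.arange(1, self.n + 1) / self.n))
        for t in range(1, self.n + 1):
            out[t] = out[t - 1] @ Pi[t - 1]
        return out

    def simulate(self, n: int | None = None, initial: int | None = None,
                 seed: int | None = None) -> PatternLabelSequence:
        """Draw a label sequence of ``n`` transitions from the fitted drift."""
        n = self.n if n is None else int(n)
        if initial is None:
            initial = int(self.model.data.labels[0]) if self.model is not None else 1
        return simulate_labels(self.supports, n, initial, seed=seed)

    def information_criteria(self, seq=None) -> ModelScore:
        """Score a sequence (default: the training data) under this model."""
        if seq is None:
            if self.model is None:
                raise ValueError("no training data attached; pass a sequence")
            return self.score
        seq = _as_sequence(seq, m=self.m)
        helper = DriftingMarkov(seq, degree=self.degree, m=self.m,
                                floor=self._floor if self.model is None
                                else self.model.floor)
        return helper.loglike(self.supports)

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "schema": "motorexplore.dmm/1",
            "m": self.m,
            "degree": self.degree,
            "n": self.n,
            "supports": self.supports.tolist(),
            "loglik": None if self.score is None else self.score.loglik,
            "converged": self.converged,
            "nit": self.nit,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DriftingMarkovResults":
        payload = json.loads(text)
        if payload.get("schema") != "motorexplore.dmm/1":
            raise ValueError("unrecognized model schema")
        return cls.from_supports(np.array(payload["supports"]), n=payload["n"])

    def plot_appearance(self, p0=None, ax=None):
        """Plot the probability of appearance of each pattern along the
        sequence (one line per pattern)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        probs = self.appearance_probabilities(p0)
        for k in range(self.m):
            ax.plot(probs[:, k], label=f"pattern {k + 1}", lw=1.2)
        ax.set_xlabel("cycle")
        ax.set_ylabel("appearance probability")
        ax.set_ylim(0, 1)
        ax.legend(fontsize="small", ncol=2)
        return ax

    def summary(self) -> str:
        s = self.score
        lines = [
            "Drifting Markov model (order 1)",
            f"  alphabet size m: {self.m}",
            f"  drift degree d:  {self.degree}",
            f"  transitions n:   {self.n}",
        ]
        if s is not None:
            lines += [
                f"  log-likelihood:  {s.loglik:.4f}",
                f"  parameters:      {s.npar}",
                f"  AIC:             {s.aic:.4f}",
                f"  BIC:             {s.bic:.4f}",
            ]
        lines.append(f"  converged:       {self.converged} ({self.nit} iterations)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# convenience functions


def fit_dmm(seq, degree: int, m: int | None = None, **kwargs
            ) -> DriftingMarkovResults:
    """Fit a drifting Markov model of the given degree to a label sequence."""
    return DriftingMarkov(seq, degree=degree, m=m).fit(**kwargs)


def simulate_labels(supports, n: int, initial: int, seed=None
                    ) -> PatternLabelSequence:
    """Simulate ``n`` transitions from drifting supports, starting at
    ``initial`` (1-based)."""
    supports = np.asarray(supports, dtype=float)
    m = supports.shape[1]
    if not 1 <= initial <= m:
        raise ValueError(f"initial state must be in 1..{m}")
    rng = np.random.default_rng(seed)
    Pi = _clip_renorm(_interp_supports(supports, np.arange(1, n + 1) / n))
    labels = np.empty(n + 1, dtype=np.int64)
    labels[0] = initial
    draws = rng.random(n)
    for t in range(1, n + 1):
        cdf = np.cumsum(Pi[t - 1, labels[t - 1] - 1])
        labels[t] = np.searchsorted(cdf, draws[t - 1] * cdf[-1]) + 1
    return PatternLabelSequence(labels, m=m)
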