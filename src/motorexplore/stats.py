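"""Inferential statistics for the motor-learning analyses.

Covers the comparisons the analysis pipeline reports: paired t tests on
learning rates, Levene's test (mean-centered, i.e. the original statistic)
for equality of variances, a fully within-subject two-way ANOVA with
partial eta squared and sphericity handling (Greenhouse-Geisser /
Huynh-Feldt), Bonferroni-corrected pairwise post hocs, Pearson/Spearman
correlations and Cohen's d.  Everything returns a :class:`TestResult` so
reports serialize uniformly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "WithinSubjectTable",
    "paired_t",
    "sample_variance",
    "levene_mean_centered",
    "rm_anova2",
    "bonferroni_pairwise",
    "correlation",
    "cohens_d",
    "shapiro_normality",
]


@dataclass
class TestResult:
    """A single inferential test: statistic, dfs, p, effect size, CI."""

    name: str
    statistic: float
    df: tuple | float
    p: float
    effect_size: float | None = None
    ci95: tuple | None = None
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:
        df = self.df if not isinstance(self.df, tuple) else \
            ", ".join(f"{d:g}" for d in self.df)
        s = f"{self.name}: stat = {self.statistic:.4f}, df = ({df}), p = {self.p:.4g}"
        if self.effect_size is not None:
            s += f", effect = {self.effect_size:.4f}"
        return s

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p,
            "effect_size": self.effect_size,
            "ci95": list(self.ci95) if self.ci95 else None,
            **({"extras": self.extras} if self.extras else {}),
        }


# ---------------------------------------------------------------------------
# simple tests


def paired_t(x, y) -> TestResult:
    """Two-sided paired-sample t test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero-variance differences: paired t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult("paired t", float(t), float(n - 1), float(p))


def sample_variance(x) -> float:
    """Unbiased sample variance (n - 1 denominator)."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need at least two values")
    return float(np.var(x, ddof=1))


def levene_mean_centered(groups, center: str = "mean") -> TestResult:
    """Levene's test for equality of variances.

    ``center="mean"`` is Levene's original statistic (a one-way ANOVA on
    absolute deviations from the group mean); ``center="median"`` gives the
    Brown-Forsythe variant.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    N = sum(g.size for g in groups)
    z = [np.abs(g - (np.mean(g) if center == "mean" else np.median(g)))
         for g in groups]
    within = sum(float(np.sum((zi - zi.mean()) ** 2)) for zi in z)
    grand = np.concatenate(z).mean()
    between = sum(zi.size * (zi.mean() - grand) ** 2 for zi in z)
    if within <= 0:
        if between <= 0:
            return TestResult("Levene", 0.0, (k - 1, N - k), 1.0,
                              extras={"degenerate": True})
        return TestResult("Levene", np.inf, (k - 1, N - k), 0.0,
                          extras={"degenerate": True})
    F = (between / (k - 1)) / (within / (N - k))
    p = sps.f.sf(F, k - 1, N - k)
    return TestResult("Levene", float(F), (k - 1, N - k), float(p),
                      extras={"center": center})


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson's r or Spearman's rho with a two-sided p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a variable: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        name = "Pearson r"
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
        name = "Spearman rho"
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestResult(name, float(r), float(x.size - 2), float(p))


def cohens_d(x, y, paired: bool = False) -> float:
    """Cohen's d: paired uses mean/SD of the differences, unpaired the
    mean difference over the pooled SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired d needs equal lengths")
        d = x - y
        sd = d.std(ddof=1)
        if sd <= 0:
            raise ValueError("zero SD of differences: d undefined "
                             f"(constant difference {d.mean():.4g})")
        return float(d.mean() / sd)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired d needs >= 2 values per group")
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled <= 0:
        raise ValueError("zero pooled SD: d undefined")
    return float((x.mean() - y.mean()) / pooled)


def shapiro_normality(x, alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk screening for normality (reported, never auto-switching)."""
    x = np.asarray(x, float)
    W, p = sps.shapiro(x)
    return TestResult("Shapiro-Wilk", float(W), float(x.size), float(p),
                      extras={"normal_at_alpha": bool(p > alpha),
                              "alpha": alpha})


# ---------------------------------------------------------------------------
# within-subject two-way ANOVA


@dataclass
class WithinSubjectTable:
    """Balanced complete subject x A x B table of one value per cell."""

    values: np.ndarray              # (s, a, b)
    subjects: list
    a_levels: list
    b_levels: list
    a_name: str = "A"
    b_name: str = "B"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a (subjects, A, B) cube")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("table incomplete: missing cells")
        if self.values.shape[0] < 2:
            raise ValueError("need at least two subjects")

    @classmethod
    def from_frame(cls, df, subject: str, a: str, b: str, value: str
                   ) -> "WithinSubjectTable":
        """Build from a long-format DataFrame; raises if any (subject, cell)
        is missing or duplicated."""
        import pandas as pd

        piv = df.pivot_table(index=subject, columns=[a, b], values=value,
                             aggfunc=len)
        if piv.isna().any().any() or (piv != 1).any().any():
            raise ValueError("table must contain every (subject, cell) "
                             "exactly once")
        subjects = sorted(df[subject].unique())
        a_levels = sorted(df[a].unique())
        b_levels = sorted(df[b].unique())
        cube = np.empty((len(subjects), len(a_levels), len(b_levels)))
        idx = df.set_index([subject, a, b])[value]
        for i, s in enumerate(subjects):
            for j, ai in enumerate(a_levels):
                for k, bi in enumerate(b_levels):
                    cube[i, j, k] = idx.loc[(s, ai, bi)]
        return cls(cube, subjects, a_levels, b_levels, a_name=a, b_name=b)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal rows, each orthogonal to the constant vector."""
    H = np.linalg.qr(np.column_stack([np.ones(k),
                                      np.eye(k)[:, : k - 1]]))[0][:, 1:]
    return H.T


def _sphericity(Y: np.ndarray, C: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilons for contrasted data.

    ``Y`` is subjects x cells; ``C`` the orthonormal effect contrast.
    """
    n, _ = Y.shape
    q = C.shape[0]
    Sigma = np.cov(Y, rowvar=False, ddof=1)
    M = C @ Sigma @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0, 1.0
    gg = float(tr**2 / (q * tr2))
    gg = min(max(gg, 1.0 / q), 1.0)
    denom = q * (n - 1 - q * gg)
    hf = 1.0 if denom <= 0 else float((n * q * gg - 2) / denom)
    hf = min(max(hf, gg), 1.0)
    return gg, hf


def _effect_result(name, ss_eff, df_eff, ss_err, df_err, Y_cells, C
                   ) -> TestResult:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
    eta_p2 = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    extras: dict = {"SS_effect": ss_eff, "SS_error": ss_err}
    if df_eff > 1:
        gg, hf = _sphericity(Y_cells, C)
        eps = gg if gg < 0.75 else hf
        extras.update({"eps_gg": gg, "eps_hf": hf, "eps_used": eps,
                       "correction": "greenhouse-geisser" if gg < 0.75
                       else "huynh-feldt"})
        df_used = (df_eff * eps, df_err * eps)
    else:
        df_used = (df_eff, df_err)
        extras["correction"] = "none (2 levels)"
    p = float(sps.f.sf(F, *df_used)) if np.isfinite(F) else 0.0
    return TestResult(name, float(F), (float(df_used[0]), float(df_used[1])),
                      p, effect_size=float(eta_p2), extras=extras)


def rm_anova2(table: WithinSubjectTable) -> dict[str, TestResult]:
    """Two-way fully within-subject ANOVA.

    Decomposes the subject x A x B cube into main effects, the interaction,
    and their subject-interaction error terms; F for each effect uses its
    own subject x effect error.  Partial eta squared is
    SS_effect / (SS_effect + SS_error).  For effects with more than one
    numerator df, sphericity epsilons are computed from the per-subject
    contrasted covariance and the p value uses Greenhouse-Geisser-corrected
    dfs when eps_GG < 0.75, Huynh-Feldt otherwise; 2-level effects are
    exempt.
    """
    Y = table.values
    s, a, b = Y.shape
    g = Y.mean()
    mA = Y.mean(axis=(0, 2))
    mB = Y.mean(axis=(0, 1))
    mS = Y.mean(axis=(1, 2))
    mSA = Y.mean(axis=2)
    mSB = Y.mean(axis=1)
    mAB = Y.mean(axis=0)

    ss_A = s * b * np.sum((mA - g) ** 2)
    ss_B = s * a * np.sum((mB - g) ** 2)
    ss_S = a * b * np.sum((mS - g) ** 2)
    ss_SA = b * np.sum((mSA - mA[None, :] - mS[:, None] + g) ** 2)
    ss_SB = a * np.sum((mSB - mB[None, :] - mS[:, None] + g) ** 2)
    ss_AB = s * np.sum((mAB - mA[:, None] - mB[None, :] + g) ** 2)
    ss_tot = np.sum((Y - g) ** 2)
    ss_SAB = ss_tot - ss_A - ss_B - ss_S - ss_SA - ss_SB - ss_AB
    # exact degeneracies (e.g. a factor constant across its levels) leave
    # rounding residue whose ratio would be a meaningless F
    tiny = 1e-12 * max(ss_tot, 1.0)
    ss_A, ss_B, ss_AB = (0.0 if s < tiny else s for s in (ss_A, ss_B, ss_AB))
    ss_SA, ss_SB, ss_SAB = (0.0 if s < tiny else s
                            for s in (ss_SA, ss_SB, ss_SAB))

    CA = _orthonormal_contrasts(a)
    CB = _orthonormal_contrasts(b)
    onesA = np.full((1, a), 1 / np.sqrt(a))
    onesB = np.full((1, b), 1 / np.sqrt(b))

    YA = Y.mean(axis=2)                      # subjects x a
    YB = Y.mean(axis=1)
    Ycells = Y.reshape(s, a * b)

    out = {
        table.a_name: _effect_result(
            table.a_name, ss_A, a - 1, ss_SA, (a - 1) * (s - 1), YA, CA),
        table.b_name: _effect_result(
            table.b_name, ss_B, b - 1, ss_SB, (b - 1) * (s - 1), YB, CB),
        f"{table.a_name} x {table.b_name}": _effect_result(
            f"{table.a_name} x {table.b_name}", ss_AB, (a - 1) * (b - 1),
            ss_SAB, (a - 1) * (b - 1) * (s - 1), Ycells,
            np.kron(CA, CB)),
    }
    for r in out.values():
        r.extras["SS_total"] = float(ss_tot)
        r.extras["SS_subject"] = float(ss_S)
    return out


@dataclass
class PairwiseComparison:
    pair: tuple
    mean_difference: float
    ci95: tuple
    p_raw: float
    p_adjusted: float
    t: float
    df: int


def bonferroni_pairwise(table: WithinSubjectTable, factor: str
                        ) -> list[PairwiseComparison]:
    """Bonferroni-corrected paired comparisons between the levels of one
    within-subject factor (collapsing over the other).

    Each comparison is a paired t on per-subject level means; the CI is the
    per-pair paired-t 95% interval; p values are multiplied by the number
    of pairs and capped at 1.
    """
    if factor == table.a_name:
        Y = table.values.mean(axis=2)
        levels = table.a_levels
    elif factor == table.b_name:
        Y = table.values.mean(axis=1)
        levels = table.b_levels
    else:
        raise ValueError(f"unknown factor {factor!r}")
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    pairs = list(itertools.combinations(range(k), 2))
    npairs = len(pairs)
    out = []
    n = Y.shape[0]
    tcrit = sps.t.ppf(0.975, n - 1)
    for i, j in pairs:
        d = Y[:, i] - Y[:, j]
        md = float(d.mean())
        se = d.std(ddof=1) / np.sqrt(n)
        if se > 0:
            t = md / se
            p = 2.0 * sps.t.sf(abs(t), n - 1)
        else:
            t, p = (0.0, 1.0) if md == 0 else (np.inf, 0.0)
        ci = (md - tcrit * se, md + tcrit * se)
        out.append(PairwiseComparison(
            pair=(levels[i], levels[j]), mean_difference=md,
            ci95=(float(ci[0]), float(ci[1])), p_raw=float(p),
            p_adjusted=float(min(1.0, p * npairs)), t=float(t), df=n - 1))
    return out
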