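"""Inferential statistics: paired t, Levene, within-subject ANOVA, etc."""

import itertools

import numpy as np
import pytest

from motorexplore import (WithinSubjectTable, bonferroni_pairwise, cohens_d,
                          correlation, levene_mean_centered, paired_t,
                          rm_anova2, sample_variance)


class TestPairedT:
    def test_symmetric_differences(self):
        res = paired_t([1, 2, 3], [3, 2, 1])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert paired_t(x, y).statistic == pytest.approx(
            -paired_t(y, x).statistic)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0])

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        x, y = rng.normal(size=(2, 12))
        mine = paired_t(x, y)
        ref = ttest_rel(x, y)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)


class TestVarianceAndLevene:
    def test_sample_variance(self):
        assert sample_variance([1, 2, 3]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sample_variance([1.0])

    def test_identical_groups_f_zero(self):
        res = levene_mean_centered([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_scipy_mean_centered(self, rng):
        from scipy.stats import levene

        a = rng.normal(size=9)
        b = rng.normal(0.0, 3.0, size=9)
        mine = levene_mean_centered([a, b])
        ref = levene(a, b, center="mean")
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_degenerate_infinite_f(self):
        res = levene_mean_centered([[0.0, 0.0], [-1.0, 1.0]])
        assert np.isinf(res.statistic)
        assert res.extras["degenerate"]

    def test_shift_and_relabel_invariance(self, rng):
        groups = [rng.normal(size=8), rng.normal(0, 2, size=8)]
        base = levene_mean_centered(groups).statistic
        shifted = levene_mean_centered(
            [groups[0] + 5.0, groups[1] - 3.0]).statistic
        swapped = levene_mean_centered(groups[::-1]).statistic
        assert shifted == pytest.approx(base)
        assert swapped == pytest.approx(base)


class TestCorrelationAndD:
    def test_linear_pearson(self):
        x = np.arange(10.0)
        assert correlation(x, 2 * x + 1).statistic == pytest.approx(1.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(-2, 2, 15)
        rho = correlation(x, x**3, method="spearman")
        r = correlation(x, x**3, method="pearson")
        assert rho.statistic == pytest.approx(1.0)
        assert r.statistic < 1.0

    def test_sampling_check(self):
        rng = np.random.default_rng(0)
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=10000)
        r = correlation(xy[:, 0], xy[:, 1]).statistic
        assert abs(r - 0.5) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1], [1, 2, 3])

    def test_cohens_d_paired_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = x - np.array([0.5 - 1.0, 0.5, 0.5 + 1.0])
        d = cohens_d(x, y, paired=True)
        assert d == pytest.approx(0.5)

    def test_cohens_d_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            cohens_d(x, x, paired=True)
        with pytest.raises(ValueError):
            cohens_d(x, x + 1.0, paired=True)

    def test_cohens_d_unpaired_sampling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 10000)
        y = rng.normal(0.0, 1.0, 10000)
        assert abs(cohens_d(x, y) - 1.0) < 0.05


def _cube(rng, s=7, a=2, b=2):
    return WithinSubjectTable(rng.normal(size=(s, a, b)),
                              subjects=list(range(s)),
                              a_levels=list(range(a)),
                              b_levels=list(range(b)))


def brute_force_ss(Y):
    """Independent oracle: SS decomposition via explicit cell-mean model."""
    s, a, b = Y.shape
    g = Y.mean()
    ss = {}
    ss["A"] = s * b * ((Y.mean(axis=(0, 2)) - g) ** 2).sum()
    ss["B"] = s * a * ((Y.mean(axis=(0, 1)) - g) ** 2).sum()
    ss["S"] = a * b * ((Y.mean(axis=(1, 2)) - g) ** 2).sum()
    ss["AB"] = s * ((Y.mean(axis=0) - Y.mean(axis=(0, 2))[:, None]
                     - Y.mean(axis=(0, 1))[None, :] + g) ** 2).sum()
    ss["AS"] = b * ((Y.mean(axis=2) - Y.mean(axis=(0, 2))[None, :]
                     - Y.mean(axis=(1, 2))[:, None] + g) ** 2).sum()
    ss["BS"] = a * ((Y.mean(axis=1) - Y.mean(axis=(0, 1))[None, :]
                     - Y.mean(axis=(1, 2))[:, None] + g) ** 2).sum()
    ss["total"] = ((Y - g) ** 2).sum()
    ss["ABS"] = ss["total"] - sum(ss[k] for k in
                                  ("A", "B", "S", "AB", "AS", "BS"))
    return ss


class TestRmAnova2:
    def test_ss_decomposition_against_brute_force(self, rng):
        table = _cube(rng, s=7, a=3, b=4)
        out = rm_anova2(table)
        ss = brute_force_ss(table.values)
        assert out["A"].extras["SS_effect"] == pytest.approx(ss["A"])
        assert out["A"].extras["SS_error"] == pytest.approx(ss["AS"])
        assert out["B"].extras["SS_effect"] == pytest.approx(ss["B"])
        assert out["B"].extras["SS_error"] == pytest.approx(ss["BS"])
        assert out["A x B"].extras["SS_effect"] == pytest.approx(ss["AB"])
        assert out["A x B"].extras["SS_error"] == pytest.approx(ss["ABS"])
        total = sum(ss[k] for k in ("A", "B", "S", "AB", "AS", "BS", "ABS"))
        assert total == pytest.approx(ss["total"])

    def test_two_level_factor_equals_paired_t_squared(self, rng):
        table = _cube(rng, s=8, a=2, b=3)
        out = rm_anova2(table)
        x = table.values[:, 0, :].mean(axis=1)
        y = table.values[:, 1, :].mean(axis=1)
        t = paired_t(x, y)
        assert out["A"].statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert out["A"].p == pytest.approx(t.p, abs=1e-12)

    def test_constant_factor_f_zero(self):
        Y = np.random.default_rng(8).normal(size=(6, 3, 1))
        Y = np.repeat(Y, 2, axis=2)  # factor B constant across its levels
        out = rm_anova2(WithinSubjectTable(Y, list(range(6)), [0, 1, 2],
                                           [0, 1]))
        assert out["B"].statistic == pytest.approx(0.0)

    def test_partial_eta_squared_in_unit_interval(self, rng):
        for _ in range(5):
            out = rm_anova2(_cube(rng, s=5, a=3, b=3))
            for r in out.values():
                assert 0.0 <= r.effect_size <= 1.0
                assert 0.0 <= r.p <= 1.0

    def test_sphericity_epsilon_bounds(self, rng):
        out = rm_anova2(_cube(rng, s=10, a=5, b=2))
        ex = out["A"].extras
        q = 4
        assert 1.0 / q <= ex["eps_gg"] <= 1.0
        assert ex["eps_gg"] <= ex["eps_hf"] <= 1.0

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        Y = rng.normal(size=(7, 2, 2))
        rows = [
            {"subject": s, "A": i, "B": j, "y": Y[s, i, j]}
            for s in range(7) for i in range(2) for j in range(2)
        ]
        df = pd.DataFrame(rows)
        ref = pg.rm_anova(dv="y", within=["A", "B"], subject="subject",
                          data=df, detailed=True)
        out = rm_anova2(WithinSubjectTable(Y, list(range(7)), [0, 1],
                                           [0, 1]))
        for name, key in (("A", "A"), ("B", "B"), ("A x B", "A * B")):
            row = ref[ref["Source"] == key].iloc[0]
            assert out[name].statistic == pytest.approx(row["F"], rel=1e-6)

    def test_incomplete_table_rejected(self):
        Y = np.full((3, 2, 2), np.nan)
        with pytest.raises(ValueError):
            WithinSubjectTable(Y, [0, 1, 2], [0, 1], [0, 1])


class TestBonferroni:
    def test_two_levels_unadjusted(self, rng):
        table = _cube(rng, s=8, a=2, b=2)
        out = bonferroni_pairwise(table, "A")
        assert len(out) == 1
        assert out[0].p_adjusted == pytest.approx(out[0].p_raw)

    def test_pair_count_and_alpha(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(7, 11, 2))
        table = WithinSubjectTable(Y, list(range(7)), list(range(11)),
                                   [0, 1])
        out = bonferroni_pairwise(table, "A")
        assert len(out) == 55

    def test_against_per_pair_oracle(self, rng):
        table = _cube(rng, s=9, a=4, b=2)
        out = bonferroni_pairwise(table, "A")
        Y = table.values.mean(axis=2)
        pairs = list(itertools.combinations(range(4), 2))
        for comp, (i, j) in zip(out, pairs):
            t = paired_t(Y[:, i], Y[:, j])
            assert comp.t == pytest.approx(t.statistic)
            assert comp.p_adjusted == pytest.approx(
                min(1.0, t.p * len(pairs)))
            assert comp.p_adjusted >= comp.p_raw
            assert comp.ci95[0] <= comp.mean_difference <= comp.ci95[1]
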