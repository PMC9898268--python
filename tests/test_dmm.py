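"""Drifting Markov models: estimation, evaluation, simulation."""

import numpy as np
import pytest

from motorexplore import (DriftingMarkov, DriftingMarkovResults,
                          PatternLabelSequence, fit_dmm, simulate_labels)
from motorexplore.dmm import lagrange_weights


def count_mle(labels, m):
    """Independent oracle: transition-count ratio estimate."""
    C = np.zeros((m, m))
    for a, b in zip(labels[:-1], labels[1:]):
        C[a - 1, b - 1] += 1
    rows = C.sum(axis=1, keepdims=True)
    out = np.full((m, m), 1.0 / m)
    nz = rows[:, 0] > 0
    out[nz] = C[nz] / rows[nz]
    return out


class TestSequences:
    def test_from_string_nucleotides(self):
        seq = PatternLabelSequence.from_string("acgtacgt")
        assert seq.m == 4 and seq.n == 7
        assert seq.meta["alphabet"] == "acgt"

    def test_label_bounds_enforced(self):
        with pytest.raises(ValueError):
            PatternLabelSequence(np.array([1, 5]), m=3)

    def test_visited_mask(self):
        seq = PatternLabelSequence(np.array([1, 2, 2, 3]), m=5)
        assert seq.visited().tolist() == [True, True, True, False, False]


class TestLagrange:
    def test_weights_sum_to_one(self):
        s = np.linspace(0, 1, 57)
        for d in (1, 2, 3, 5):
            W = lagrange_weights(s, d)
            assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_support_points_are_exact(self):
        for d in (1, 3):
            W = lagrange_weights(np.arange(d + 1) / d, d)
            assert np.allclose(W, np.eye(d + 1), atol=1e-12)


class TestFit:
    def test_degree0_equals_count_mle(self):
        labels = [1, 1, 2, 1, 2, 2]
        res = fit_dmm(labels, degree=0)
        expected = np.array([[1 / 3, 2 / 3], [1 / 2, 1 / 2]])
        assert np.allclose(res.supports[0], expected, atol=1e-12)

    def test_degree0_equals_count_mle_random(self, rng):
        labels = rng.integers(1, 4, size=300)
        res = fit_dmm(labels, degree=0, m=3)
        assert np.allclose(res.supports[0], count_mle(labels, 3), atol=1e-12)

    def test_constant_sequence_degree1(self):
        res = fit_dmm([1, 1, 1, 1], degree=1, m=2)
        assert res.supports[0][0, 0] > 0.999
        assert res.supports[1][0, 0] > 0.999

    def test_supports_row_stochastic(self, rng):
        labels = rng.integers(1, 5, size=400)
        for d in (0, 1, 2, 3):
            res = fit_dmm(labels, degree=d, m=4)
            assert np.allclose(res.supports.sum(axis=2), 1.0, atol=1e-9)

    def test_sequence_too_short(self):
        with pytest.raises(ValueError):
            DriftingMarkov([1, 2], degree=3, m=2)

    def test_degree1_recovers_known_drift(self):
        P0 = np.array([[0.9, 0.1], [0.2, 0.8]])
        P1 = np.array([[0.3, 0.7], [0.6, 0.4]])
        seq = simulate_labels(np.stack([P0, P1]), 5000, 1, seed=4)
        res = fit_dmm(seq, degree=1, m=2)
        assert np.abs(res.supports - np.stack([P0, P1])).max() < 0.05

    def test_homogeneous_data_gives_vanishing_drift(self):
        # drift estimate converges to zero for data from a homogeneous
        # chain; n chosen so the endpoint sampling noise sits below 0.05
        P = np.array([[0.7, 0.3], [0.4, 0.6]])
        seq = simulate_labels(P[None], 30000, 1, seed=0)
        res = fit_dmm(seq, degree=1, m=2)
        assert np.abs(res.supports[0] - res.supports[1]).max() < 0.05

    def test_least_squares_variant_close_to_ml(self):
        P0 = np.array([[0.9, 0.1], [0.2, 0.8]])
        P1 = np.array([[0.3, 0.7], [0.6, 0.4]])
        seq = simulate_labels(np.stack([P0, P1]), 4000, 1, seed=9)
        ml = DriftingMarkov(seq, degree=1, m=2).fit()
        ls = DriftingMarkov(seq, degree=1, m=2).fit(method="ls")
        assert np.abs(ml.supports - ls.supports).max() < 0.1


class TestTransitionAt:
    def setup_method(self):
        self.P0 = np.array([[0.9, 0.1], [0.2, 0.8]])
        self.P1 = np.array([[0.1, 0.9], [0.6, 0.4]])
        self.res = DriftingMarkovResults.from_supports(
            np.stack([self.P0, self.P1]), n=100)

    def test_endpoints_and_midpoint(self):
        assert np.allclose(self.res.transition_at(0), self.P0)
        assert np.allclose(self.res.transition_at(100), self.P1)
        assert np.allclose(self.res.transition_at(50),
                           (self.P0 + self.P1) / 2)

    def test_degree3_hits_interior_support(self):
        rng = np.random.default_rng(2)
        sup = rng.dirichlet(np.ones(3), size=(4, 3))
        res = DriftingMarkovResults.from_supports(sup, n=300)
        assert np.allclose(res.transition_at(200), sup[2], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            self.res.transition_at(101)

    def test_rows_sum_to_one_on_dense_grid(self, rng):
        labels = rng.integers(1, 4, size=600)
        for d in (1, 3):
            res = fit_dmm(labels, degree=d, m=3)
            Pi = res.transition_at(np.linspace(0, res.n, 1000))
            assert np.allclose(Pi.sum(axis=2), 1.0, atol=1e-9)
            assert Pi.min() >= 0.0


class TestAppearance:
    def test_identity_is_absorbing(self):
        res = DriftingMarkovResults.from_supports(np.eye(2)[None], n=10)
        probs = res.appearance_probabilities(p0=np.array([1.0, 0.0]))
        assert np.allclose(probs, np.tile([1.0, 0.0], (11, 1)))

    def test_uniform_matrix_mixes_in_one_step(self):
        P = np.full((1, 2, 2), 0.5)
        res = DriftingMarkovResults.from_supports(P, n=5)
        probs = res.appearance_probabilities(p0=np.array([1.0, 0.0]))
        assert np.allclose(probs[1:], 0.5)

    def test_hand_propagation_degree1(self):
        sup = np.array([[[1.0, 0.0], [0.0, 1.0]],
                        [[0.0, 1.0], [0.0, 1.0]]])
        res = DriftingMarkovResults.from_supports(sup, n=2)
        probs = res.appearance_probabilities(p0=np.array([1.0, 0.0]))
        assert np.allclose(probs, [[1, 0], [0.5, 0.5], [0, 1]])

    def test_rows_are_distributions(self, rng):
        labels = rng.integers(1, 4, size=500)
        res = fit_dmm(labels, degree=3, m=3)
        probs = res.appearance_probabilities()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0

    def test_invalid_p0_rejected(self):
        res = DriftingMarkovResults.from_supports(np.eye(2)[None], n=10)
        with pytest.raises(ValueError):
            res.appearance_probabilities(p0=np.array([0.5, 0.2]))


class TestSimulate:
    def test_identity_freezes_state(self):
        seq = simulate_labels(np.eye(3)[None], 50, 2, seed=0)
        assert np.all(seq.labels == 2)

    def test_seeded_determinism(self):
        sup = np.random.default_rng(5).dirichlet(np.ones(3), size=(2, 3))
        a = simulate_labels(sup, 200, 1, seed=42)
        b = simulate_labels(sup, 200, 1, seed=42)
        assert np.array_equal(a.labels, b.labels)

    def test_law_of_large_numbers(self):
        P = np.array([[0.7, 0.3], [0.4, 0.6]])
        seq = simulate_labels(P[None], 100000, 1, seed=3)
        emp = count_mle(seq.labels, 2)
        assert np.abs(emp - P).max() < 0.01

    def test_invalid_initial_state(self):
        with pytest.raises(ValueError):
            simulate_labels(np.eye(2)[None], 10, 3, seed=0)


class TestScores:
    def test_certain_transition_loglik_zero(self):
        sup = np.array([[[0.0, 1.0], [0.5, 0.5]]])
        res = DriftingMarkovResults.from_supports(sup, n=1, floor=0.0)
        score = res.information_criteria([1, 2])
        assert score.loglik == pytest.approx(0.0)
        assert score.aic == pytest.approx(2 * score.npar)

    def test_npar_formula(self, rng):
        labels = rng.integers(1, 12, size=2000)
        res = fit_dmm(labels, degree=3, m=11)
        assert res.score.npar == 440

    def test_zero_probability_transition_diagnosed(self):
        sup = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        res = DriftingMarkovResults.from_supports(sup, n=2, floor=0.0)
        score = res.information_criteria([1, 2, 2])
        assert score.loglik == -np.inf
        assert score.zero_transitions == [(1, 1, 2)]

    def test_nested_degrees_loglik_ordering(self, rng):
        for trial in range(3):
            labels = rng.integers(1, 4, size=300)
            r1 = fit_dmm(labels, degree=1, m=3)
            r3 = fit_dmm(labels, degree=3, m=3)
            assert r3.loglik >= r1.loglik - 1e-6

    def test_json_round_trip(self, rng):
        labels = rng.integers(1, 4, size=200)
        res = fit_dmm(labels, degree=2, m=3)
        clone = DriftingMarkovResults.from_json(res.to_json())
        assert np.allclose(clone.supports, res.supports)
        assert clone.n == res.n
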