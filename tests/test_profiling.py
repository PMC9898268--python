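"""Coordination-profile clustering and BIC plateau selection."""

import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from motorexplore import (assign_labels, fit_profiles, model_bic, select_k)
from motorexplore.datasets import coordination_bic_curve
from motorexplore.profiling import FisherEM, circular_mean_deg


class TestFisherEM:
    def test_two_families_perfectly_separated(self, crp_two_families):
        X, truth = crp_two_families
        res = fit_profiles(X, 2, seed=0)
        labels, profiles = assign_labels(res)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert sum(p.member_count for p in profiles) == len(X)

    def test_k1_single_component(self, crp_two_families):
        X, _ = crp_two_families
        res = fit_profiles(X, 1, seed=0)
        assert np.allclose(res.responsibilities, 1.0)
        assert np.isfinite(res.bic)

    def test_identical_curves_degenerate_warning(self):
        X = np.zeros((30, 50))
        with pytest.warns(UserWarning, match="degenerate"):
            res = fit_profiles(X, 2, seed=0, span_tol=None)
        labels, _ = assign_labels(res)
        assert len(set(labels)) == 1

    def test_determinism_given_seed(self, crp_two_families):
        X, _ = crp_two_families
        a = fit_profiles(X, 3, seed=7, n_init=3)
        b = fit_profiles(X, 3, seed=7, n_init=3)
        assert a.loglik == b.loglik
        assert np.array_equal(a.predict_raw(), b.predict_raw())

    def test_loglik_nondecreasing_along_em_path(self, crp_two_families):
        X, _ = crp_two_families
        res = fit_profiles(X, 3, seed=1, n_init=2)
        path = np.array(res.ll_path)
        assert np.all(np.diff(path) >= -1e-7 * np.abs(path[:-1]))

    def test_projection_orthonormal(self, crp_two_families):
        X, _ = crp_two_families
        res = fit_profiles(X, 3, seed=2)
        U = res.projection
        assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-9)

    def test_weights_sum_to_one(self, crp_two_families):
        X, _ = crp_two_families
        res = fit_profiles(X, 3, seed=2)
        assert np.isclose(res.weights.sum(), 1.0)

    def test_assignment_invariant_to_basis_rotation(self, crp_two_families):
        # rotating the latent basis (and parameters with it) leaves the
        # component assignment unchanged
        X, _ = crp_two_families
        res = fit_profiles(X, 2, seed=0)
        before = res.predict_raw()
        d = res.projection.shape[1]
        rng = np.random.default_rng(0)
        R, _ = np.linalg.qr(rng.normal(size=(d, d)))
        res.projection = res.projection @ R
        res.means = res.means @ R
        res.covariances = np.einsum("ij,kjl,lm->kim", R.T,
                                    res.covariances, R)
        after = res.predict_raw(res.curves_)
        assert np.array_equal(before, after)

    def test_needs_more_points_than_clusters(self):
        with pytest.raises(ValueError):
            FisherEM(np.zeros((3, 5)), 4)


class TestBIC:
    def test_single_gaussian_closed_form(self, rng):
        # closed-form Gaussian likelihood oracle for the K=1 model
        X = rng.normal(0, 2, (120, 6))
        res = fit_profiles(X, 1, seed=0, embed=None, span_tol=None)
        from scipy.stats import multivariate_normal

        U = res.projection
        S = U @ res.covariances[0] @ U.T + res.noise_variance * (
            np.eye(6) - U @ U.T)
        mu = X.mean(axis=0) + U @ res.means[0]
        ll = multivariate_normal(mu, S).logpdf(X).sum()
        assert res.loglik == pytest.approx(ll, rel=1e-9)
        assert model_bic(res) == pytest.approx(
            2 * ll - res.npar * np.log(len(X)))

    def test_nested_loglik_ordering(self, crp_two_families):
        X, _ = crp_two_families
        r1 = fit_profiles(X, 1, seed=0)
        r2 = fit_profiles(X, 2, seed=0)
        assert r2.loglik >= r1.loglik


class TestSelectK:
    def test_published_bic_vector_selects_11(self):
        assert select_k(coordination_bic_curve())[0] == 11

    def test_strictly_increasing_warns_max_k(self):
        with pytest.warns(UserWarning):
            k, flag = select_k({2: 1.0, 3: 2.0, 4: 3.0})
        assert k == 4 and flag

    def test_immediate_decrease(self):
        assert select_k({2: 5.0, 3: 4.0, 4: 3.0}) == (2, False)

    def test_empty_and_gappy_input_rejected(self):
        with pytest.raises(ValueError):
            select_k({})
        with pytest.raises(ValueError):
            select_k({2: 1.0, 4: 2.0})

    def test_recovers_true_k_on_separated_templates(self, rng):
        # templates >= 6 sigma apart: BIC plateau at the true K for
        # at least 9 of 10 seeds
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = np.vstack([r.normal(mu, 5.0, (80, 100))
                           for mu in (-120.0, -40.0, 40.0, 120.0)])
            bics = {}
            for k in range(2, 9):
                # white noise: the full space is well conditioned, no
                # span restriction needed
                bics[k] = fit_profiles(X, k, seed=seed * 31 + k,
                                       n_init=4, span_tol=None).bic
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                k_star, _ = select_k(bics)
            hits += k_star == 4
        assert hits >= 9


class TestCanonicalLabels:
    def test_relabel_by_circular_mean(self, rng):
        lo = rng.normal(-20.0, 3.0, (40, 50))
        hi = rng.normal(150.0, 3.0, (40, 50))
        X = np.vstack([hi, lo])  # reversed order on purpose
        res = fit_profiles(X, 2, seed=0)
        labels, profiles = assign_labels(res)
        assert profiles[0].pattern_id == 1
        assert profiles[0].circular_mean < profiles[1].circular_mean
        assert np.all(labels[40:] == 1)  # the -20 deg family is pattern 1
        assert np.all(labels[:40] == 2)

    def test_mean_curves_near_templates(self, rng):
        lo = rng.normal(-20.0, 3.0, (40, 50))
        hi = rng.normal(150.0, 3.0, (40, 50))
        res = fit_profiles(np.vstack([lo, hi]), 2, seed=0)
        _, profiles = assign_labels(res)
        assert np.abs(profiles[0].mean_crp - (-20.0)).max() < 3.0
        assert np.abs(profiles[1].mean_crp - 150.0).max() < 3.0

    def test_circular_mean_wraps(self):
        assert circular_mean_deg([170.0, -170.0]) == pytest.approx(180.0)
        assert circular_mean_deg([-10.0, 10.0]) == pytest.approx(0.0)

    def test_new_curves_assigned_to_their_component(self, rng):
        lo = rng.normal(-20.0, 3.0, (40, 50))
        hi = rng.normal(150.0, 3.0, (40, 50))
        res = fit_profiles(np.vstack([lo, hi]), 2, seed=0)
        labels, _ = assign_labels(res, np.vstack([lo[:5], hi[:5]]))
        assert labels.tolist() == [1] * 5 + [2] * 5
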