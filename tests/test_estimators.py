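"""EM estimation: single-state, multi-state, posteriors, state assignment."""

import numpy as np
import pytest
from scipy.integrate import quad
from sklearn.base import clone

from pnndiffusion import (PNNEstimator, assign_states, em_fit_multi,
                          em_fit_single, estimate_D_closed_form,
                          loglik_single, posterior_multi, posterior_q_single,
                          select_by_aic)
from pnndiffusion.estimators import joint_multi
from pnndiffusion.model import log_pdf_nn

DT = 0.02


def _records(rng, n, D, rho, dt=DT):
    """Draw records from the exact model at uniform density (inverse CDF of
    the nearest-neighbour distance: Δr² exponential with combined rate)."""
    rate = rho * np.pi + 1.0 / (4.0 * D * dt)
    r2 = rng.exponential(1.0 / rate, n)
    return np.column_stack([np.sqrt(r2), np.full(n, rho)])


class TestSingleState:
    def test_loglik_hand_value(self):
        # rho*pi = 1 and 1/(2 D dt) = 2 give log(2 + 2) + 0 - 1 - 1
        dt = DT
        D = 1.0 / (4.0 * dt)
        val = loglik_single([1.0], [1.0 / np.pi], D, dt)
        assert val == pytest.approx(np.log(4) - 2)

    def test_loglik_is_sum_of_log_pdf(self, rng):
        X = _records(rng, 50, 1.0, 1.0)
        expected = float(np.sum(log_pdf_nn(X[:, 0], X[:, 1], 0.7, DT)))
        assert loglik_single(X[:, 0], X[:, 1], 0.7, DT) == pytest.approx(expected)
        doubled = np.vstack([X, X])
        assert loglik_single(doubled[:, 0], doubled[:, 1], 0.7, DT) == \
            pytest.approx(2 * expected)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            loglik_single([0.0, 1.0], [1.0, 1.0], 1.0, DT)

    def test_posterior_q_reference(self):
        p0, p1 = posterior_q_single(1.0, 1.0, DT)
        assert p0 == pytest.approx(0.08 * np.pi / (1 + 0.08 * np.pi))
        assert p0 + p1 == pytest.approx(1.0)
        p0_lo, p1_lo = posterior_q_single(1e-12, 1.0, DT)
        assert p1_lo == pytest.approx(1.0)

    def test_em_fixed_point_equals_closed_form(self, rng):
        # uniform rho: EM converges to the closed-form MSDN inversion
        X = _records(rng, 2000, 1.0, 1.0)
        # effectively-zero tolerance: iterate to the floating-point fixed point
        est = PNNEstimator(dt=DT, tol=1e-300, max_iter=3000).fit(X)
        msdn = float(np.mean(X[:, 0] ** 2))
        expected = estimate_D_closed_form(msdn, 1.0, DT)
        assert est.diffusion_constants_[0] == pytest.approx(expected, rel=1e-9)

    def test_msd_limit_at_vanishing_density(self, rng):
        X = _records(rng, 500, 1.0, 1e-10)
        est = PNNEstimator(dt=DT).fit(X)
        msd_est = float(np.mean(X[:, 0] ** 2)) / (4 * DT)
        assert est.diffusion_constants_[0] == pytest.approx(msd_est, rel=1e-6)

    def test_loglik_trace_monotone(self, rng):
        X = _records(rng, 500, 0.5, 2.0)
        est = PNNEstimator(dt=DT).fit(X)
        assert np.all(np.diff(est.loglik_trace_) >= -1e-10)

    def test_permutation_invariance(self, rng):
        X = _records(rng, 300, 1.0, 1.0)
        est1 = PNNEstimator(dt=DT, random_state=0).fit(X)
        est2 = PNNEstimator(dt=DT, random_state=0).fit(X[rng.permutation(300)])
        assert est1.diffusion_constants_[0] == pytest.approx(
            est2.diffusion_constants_[0], rel=1e-6)


class TestMultiStateMachinery:
    def test_joint_normalizes_over_q_s_and_r(self):
        D = [0.2, 2.0]
        alpha = [0.3, 0.7]
        rho = 1.0
        total = 0.0
        for q in (0, 1):
            for s in (0, 1):
                val, _ = quad(lambda r: joint_multi(r, rho, q, s, D, alpha, DT),
                              0, np.inf)
                total += val
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_joint_with_infinite_state(self):
        D = [1.0, np.inf]
        alpha = [0.8, 0.2]
        # q=1 branch of the infinite-D state vanishes for all distances
        assert joint_multi(0.5, 1.0, 1, 1, D, alpha, DT) == 0.0
        # its q=0 branch is the pure background density times alpha
        r = 0.4
        expected = 0.2 * 2 * np.pi * r * np.exp(-np.pi * r ** 2)
        assert joint_multi(r, 1.0, 0, 1, D, alpha, DT) == pytest.approx(expected)
        total = 0.0
        for q in (0, 1):
            for s in (0, 1):
                val, _ = quad(lambda r: joint_multi(r, 1.0, q, s, D, alpha, DT),
                              0, np.inf)
                total += val
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_single_state_reduction_of_joint(self):
        r, rho = 0.3, 2.0
        d = 0.7
        expected0 = 2 * rho * np.pi * r * np.exp(-rho * np.pi * r ** 2
                                                 - r ** 2 / (4 * d * DT))
        expected1 = r / (2 * d * DT) * np.exp(-rho * np.pi * r ** 2
                                              - r ** 2 / (4 * d * DT))
        assert joint_multi(r, rho, 0, 0, [d], [1.0], DT) == pytest.approx(expected0)
        assert joint_multi(r, rho, 1, 0, [d], [1.0], DT) == pytest.approx(expected1)

    def test_posterior_rows_sum_to_one(self, rng):
        X = _records(rng, 100, 1.0, 1.0)
        post = posterior_multi(X[:, 0], X[:, 1], [0.2, 2.0, np.inf],
                               [0.3, 0.5, 0.2], DT)
        np.testing.assert_allclose(post.sum(axis=(1, 2)), 1.0, atol=1e-12)

    def test_m1_posterior_reduces_to_q_posterior(self, rng):
        X = _records(rng, 50, 1.0, 1.0)
        post = posterior_multi(X[:, 0], X[:, 1], [1.0], [1.0], DT)
        p0, p1 = posterior_q_single(X[:, 1], 1.0, DT)
        np.testing.assert_allclose(post[:, 0, 0], p0, rtol=1e-12)
        np.testing.assert_allclose(post[:, 1, 0], p1, rtol=1e-12)

    def test_slow_state_mass_decreasing_in_distance(self):
        grid = np.linspace(0.05, 1.5, 60)
        post = posterior_multi(grid, np.ones_like(grid), [0.2, 2.0],
                               [0.5, 0.5], DT)
        slow_mass = post[:, :, 0].sum(axis=1)
        assert np.all(np.diff(slow_mass) < 0)


class TestMultiStateFits:
    def test_m1_multi_equals_single(self, rng):
        X = _records(rng, 800, 1.0, 1.0)
        r1 = em_fit_single(X, dt=DT, random_state=0)
        r2 = em_fit_multi(X, dt=DT, n_states=1, random_state=0)
        assert r2.diffusion_constants[0] == pytest.approx(
            r1.diffusion_constants[0], rel=1e-9)
        assert r2.log_likelihood == pytest.approx(r1.log_likelihood, rel=1e-9)

    def test_weights_sum_to_one_and_states_sorted(self, rng):
        X = _records(rng, 600, 1.0, 1.0)
        est = PNNEstimator(n_states=2, noise_state=True, dt=DT,
                           random_state=0).fit(X)
        assert np.sum(est.weights_) == pytest.approx(1.0, abs=1e-12)
        finite = est.diffusion_constants_[:-1]
        assert np.all(np.diff(finite) >= 0)
        assert np.isinf(est.diffusion_constants_[-1])

    def test_aic_counts_infinite_state_weight_not_its_D(self, rng):
        X = _records(rng, 400, 1.0, 1.0)
        plain = PNNEstimator(n_states=1, dt=DT, random_state=0).fit(X)
        noisy = PNNEstimator(n_states=1, noise_state=True, dt=DT,
                             random_state=0).fit(X)
        # k = 1 (D) for the plain fit; k = 2 (D + one free weight) with noise
        assert plain.aic_ == pytest.approx(2 * 1 - 2 * plain.log_likelihood_)
        assert noisy.aic_ == pytest.approx(2 * 2 - 2 * noisy.log_likelihood_)

    def test_select_by_aic(self, rng):
        X = _records(rng, 500, 1.0, 1.0)
        r1 = em_fit_single(X, dt=DT)
        r2 = em_fit_multi(X, dt=DT, n_states=1, noise_state=True,
                          random_state=0)
        best = select_by_aic([r1, r2])
        assert best.aic == min(r1.aic, r2.aic)


class TestAssignment:
    def test_single_state_assigns_everything_to_state_zero(self, rng):
        X = _records(rng, 50, 1.0, 1.0)
        assert np.all(assign_states(X, [1.0], [1.0], DT) == 0)

    def test_far_outlier_goes_to_infinite_state(self):
        # a distance far beyond both diffusive scales but plausible for the
        # background-only state
        X = np.array([[0.05, 1.0], [2.5, 1.0]])
        labels = assign_states(X, [0.05, 0.5, np.inf], [0.4, 0.4, 0.2], DT)
        assert labels[0] == 0
        assert labels[1] == 2

    def test_predict_matches_argmax_of_proba(self, rng):
        X = _records(rng, 200, 1.0, 1.0)
        est = PNNEstimator(n_states=2, noise_state=True, dt=DT,
                           random_state=0).fit(X)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(est.predict(X), np.argmax(proba, axis=1))


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = PNNEstimator(n_states=3, noise_state=True, tol=1e-6)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        cloned.set_params(n_states=2)
        assert cloned.n_states == 2 and est.n_states == 3

    def test_unfitted_raises(self, rng):
        from sklearn.exceptions import NotFittedError
        X = _records(rng, 10, 1.0, 1.0)
        with pytest.raises(NotFittedError):
            PNNEstimator().predict(X)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            PNNEstimator().fit(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            PNNEstimator(n_states=0).fit(np.ones((5, 2)))

    def test_score_is_mean_loglik(self, rng):
        X = _records(rng, 300, 1.0, 1.0)
        est = PNNEstimator(dt=DT).fit(X)
        expected = loglik_single(X[:, 0], X[:, 1],
                                 est.diffusion_constants_[0], DT) / len(X)
        assert est.score(X) == pytest.approx(expected, rel=1e-12)
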