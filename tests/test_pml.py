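import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.stats import norm

from hrepml.pml import (
    PMLState,
    fit_pml,
    lrt_lod,
    penalized_loglik,
    select_markers,
    update_b,
    update_beta_i,
    update_hyper,
    update_sigma_n2,
)


def make_state(b, beta, sigma_n2, mu, sigma_i2, tau=1.0):
    return PMLState(
        b=np.atleast_1d(np.asarray(b, float)),
        beta=np.asarray(beta, float),
        sigma_n2=float(sigma_n2),
        mu=np.asarray(mu, float),
        sigma_i2=np.asarray(sigma_i2, float),
        tau=tau,
    )


def random_problem(seed, n=30, t=3, effects=None):
    r = np.random.default_rng(seed)
    F = np.ones((n, 1))
    X = r.integers(0, 3, size=(n, t)).astype(float)
    effects = np.zeros(t) if effects is None else np.asarray(effects, float)
    y = 5.0 + X @ effects + r.normal(size=n)
    return y, F, X


class TestPenalizedLoglik:
    def test_no_markers_reduces_to_gaussian_loglik(self):
        y, F, _ = random_problem(0, t=1)
        X = np.zeros((len(y), 0))
        state = make_state([5.0], [], 2.0, [], [])
        e = y - 5.0
        expected = norm.logpdf(e, scale=np.sqrt(2.0)).sum()
        assert abs(penalized_loglik(state, y, F, X) - expected) < 1e-10

    def test_matches_naive_density_oracle(self):
        r = np.random.default_rng(1)
        n, t = 5, 2
        y = r.normal(size=n)
        F = np.column_stack([np.ones(n), r.normal(size=n)])
        X = r.normal(size=(n, t))
        b = r.normal(size=2)
        beta = np.array([0.7, -0.2])
        mu = np.array([0.35, -0.1])
        s2 = np.array([0.2, 0.05])
        tau = 1.3
        state = make_state(b, beta, 0.8, mu, s2, tau=tau)
        mean = F @ b + X @ beta
        expected = norm.logpdf(y, loc=mean, scale=np.sqrt(0.8)).sum()
        for i in range(t):
            expected += norm.logpdf(beta[i], loc=mu[i], scale=np.sqrt(s2[i]))
            expected += norm.logpdf(mu[i], loc=0.0, scale=np.sqrt(s2[i] / tau))
        assert abs(penalized_loglik(state, y, F, X) - expected) < 1e-10

    def test_translation_invariance_through_intercept(self):
        y, F, X = random_problem(2, t=2)
        state = make_state([5.0], [0.4, 0.1], 1.0, [0.2, 0.05], [0.04, 0.0025])
        base = penalized_loglik(state, y, F, X)
        shifted = make_state([8.0], [0.4, 0.1], 1.0, [0.2, 0.05], [0.04, 0.0025])
        assert abs(penalized_loglik(shifted, y + 3.0, F, X) - base) < 1e-10

    def test_zero_prior_variance_with_mismatched_effect_is_minus_inf(self):
        y, F, X = random_problem(3, t=1)
        state = make_state([5.0], [0.5], 1.0, [0.0], [0.0])
        assert penalized_loglik(state, y, F, X) == -np.inf


class TestCoordinateUpdates:
    def test_update_b_with_zero_effects_is_phenotype_mean(self):
        y, F, X = random_problem(4, t=2)
        state = make_state([0.0], [0.0, 0.0], 1.0, [0.0, 0.0], [1.0, 1.0])
        assert abs(update_b(state, y, F, X)[0] - y.mean()) < 1e-12

    def test_update_b_matches_normal_equation_oracle(self):
        r = np.random.default_rng(5)
        n = 20
        F = np.column_stack([np.ones(n), r.normal(size=n)])
        X = r.normal(size=(n, 3))
        beta = np.array([0.3, -0.2, 0.9])
        y = r.normal(size=n)
        state = make_state([0.0, 0.0], beta, 1.0, beta / 2, beta**2 / 4)
        expected = np.linalg.inv(F.T @ F) @ F.T @ (y - X @ beta)
        np.testing.assert_allclose(update_b(state, y, F, X), expected, atol=1e-12)

    def test_update_b_zero_when_target_orthogonal_to_design(self):
        n = 8
        F = np.ones((n, 1))
        y = np.array([1.0, -1.0] * 4)
        X = np.zeros((n, 1))
        state = make_state([2.0], [0.0], 1.0, [0.0], [1.0])
        assert abs(update_b(state, y, F, X)[0]) < 1e-12

    def test_update_beta_large_prior_variance_recovers_least_squares(self):
        y, F, X = random_problem(6, t=2, effects=[1.0, 0.0])
        state = make_state([y.mean()], [0.0, 0.0], 1.0, [0.0, 0.0], [1e12, 1e12])
        got = update_beta_i(0, state, y, F, X)
        x = X[:, 0]
        partial = y - F @ state.b
        assert abs(got - (x @ partial) / (x @ x)) < 1e-6

    def test_update_beta_shrinks_toward_zero_prior(self):
        y, F, X = random_problem(7, t=1, effects=[1.0])
        ls_state = make_state([y.mean()], [0.0], 1.0, [0.0], [1e12])
        ls = update_beta_i(0, ls_state, y, F, X)
        shrunk_state = make_state([y.mean()], [0.0], 1.0, [0.0], [1e-3])
        shrunk = update_beta_i(0, shrunk_state, y, F, X)
        assert abs(shrunk) < abs(ls)

    def test_update_beta_matches_naive_formula(self):
        r = np.random.default_rng(8)
        n, t = 15, 3
        F = np.column_stack([np.ones(n), r.normal(size=n)])
        X = r.normal(size=(n, t))
        y = r.normal(size=n)
        b = r.normal(size=2)
        beta = r.normal(size=t)
        mu = r.normal(size=t)
        s2 = r.uniform(0.1, 1.0, size=t)
        sn2 = 0.7
        state = make_state(b, beta, sn2, mu, s2)
        i = 1
        x = X[:, i]
        others = y - F @ b - X @ beta + x * beta[i]
        k = sn2 / s2[i]
        expected = (x @ others + mu[i] * k) / (x @ x + k)
        assert abs(update_beta_i(i, state, y, F, X) - expected) < 1e-12

    def test_update_sigma_n2_with_zero_fit_is_mean_square(self):
        y, F, X = random_problem(9, t=1)
        state = make_state([0.0], [0.0], 1.0, [0.0], [1.0])
        assert abs(update_sigma_n2(state, y, F, X) - np.mean(y**2)) < 1e-12

    def test_update_sigma_n2_floors_perfect_fit(self):
        n = 10
        y = np.full(n, 3.0)
        F = np.ones((n, 1))
        X = np.zeros((n, 1))
        state = make_state([3.0], [0.0], 1.0, [0.0], [1.0])
        with pytest.warns(RuntimeWarning, match="floor"):
            assert update_sigma_n2(state, y, F, X) == 1e-12

    def test_update_hyper_examples(self):
        state = make_state([0.0], [0.0], 1.0, [0.0], [1.0], tau=1.0)
        assert update_hyper(0, state) == (0.0, 0.0)
        state = make_state([0.0], [2.0], 1.0, [0.0], [1.0], tau=1.0)
        mu, s2 = update_hyper(0, state)
        assert mu == 1.0 and s2 == 1.0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(beta=st.floats(-50, 50), tau=st.floats(0.01, 20))
    def test_hyper_update_closed_form_identity(self, beta, tau):
        state = make_state([0.0], [beta], 1.0, [0.0], [1.0], tau=tau)
        mu, s2 = update_hyper(0, state)
        assert abs(mu - beta / (tau + 1.0)) < 1e-12
        assert abs(s2 - 0.5 * beta**2 * tau / (tau + 1.0)) < 1e-10


class TestFitPml:
    def test_single_strong_marker_recovered(self):
        errs = []
        for seed in range(7):
            r = np.random.default_rng(seed)
            n = 200
            x = r.integers(0, 3, size=n).astype(float)
            y = 2.0 + 1.0 * x + r.normal(0, 1.0, size=n)
            state = fit_pml(y, np.ones((n, 1)), x[:, None])
            errs.append(abs(state.beta[0] - 1.0))
        assert np.median(errs) < 0.1

    def test_pure_noise_junk_markers_all_shrink_out(self):
        cleared = 0
        reps = 20
        for seed in range(reps):
            r = np.random.default_rng(100 + seed)
            n, t = 100, 10
            X = r.integers(0, 3, size=(n, t)).astype(float)
            y = r.normal(size=n)
            state = fit_pml(y, np.ones((n, 1)), X)
            if np.all(np.abs(state.beta) <= 1e-4):
                cleared += 1
        assert cleared >= 0.9 * reps

    def test_penalized_loglik_nondecreasing_over_sweeps(self):
        # strong, well-separated signals keep the active set stable, where
        # coordinate ascent guarantees monotone penalized likelihood
        r = np.random.default_rng(12)
        n = 150
        X = r.integers(0, 3, size=(n, 4)).astype(float)
        y = 1.0 + X @ np.array([1.2, -0.9, 1.0, 0.8]) + r.normal(size=n)
        state = fit_pml(y, np.ones((n, 1)), X)
        lp = np.asarray(state.lp_history)
        act = np.asarray(state.active_history)
        stable = act == act[-1]
        lp_stable = lp[stable]
        assert np.all(np.diff(lp_stable) >= -1e-9)

    def test_fixed_point_satisfies_all_update_equations(self):
        r = np.random.default_rng(13)
        n = 120
        X = r.integers(0, 3, size=(n, 3)).astype(float)
        y = 2.0 + X @ np.array([1.0, 0.0, -1.3]) + r.normal(size=n)
        F = np.ones((n, 1))
        state = fit_pml(y, F, X, tol=1e-10, max_iter=500)
        assert state.converged
        tol = 1e-6
        np.testing.assert_allclose(state.b, update_b(state, y, F, X), atol=tol)
        for i in range(3):
            if not state.active[i]:
                continue
            mu_i, s2_i = update_hyper(i, state)
            assert abs(state.mu[i] - mu_i) < tol
            assert abs(state.sigma_i2[i] - s2_i) < tol
            assert abs(state.beta[i] - update_beta_i(i, state, y, F, X)) < tol
        assert abs(state.sigma_n2 - update_sigma_n2(state, y, F, X)) < tol

    def test_deactivation_is_absorbing(self):
        r = np.random.default_rng(14)
        n = 80
        X = r.integers(0, 3, size=(n, 5)).astype(float)
        y = 1.0 + X[:, 0] * 1.5 + r.normal(size=n)
        state = fit_pml(y, np.ones((n, 1)), X, max_iter=300)
        dead = ~state.active
        assert dead.any()  # junk markers must have collapsed
        np.testing.assert_array_equal(state.beta[dead], 0.0)
        np.testing.assert_array_equal(state.sigma_i2[dead], 0.0)
        for i in np.flatnonzero(dead):
            assert update_beta_i(i, state, y, np.ones((n, 1)), X) == 0.0

    def test_deterministic_given_inputs(self):
        y, F, X = random_problem(15, t=4, effects=[1.0, 0.0, -0.8, 0.0])
        s1 = fit_pml(y, F, X)
        s2 = fit_pml(y, F, X)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        assert s1.sigma_n2 == s2.sigma_n2 and s1.iterations == s2.iterations

    def test_single_marker_fixed_point_matches_direct_maximization(self):
        # independent oracle: numerically maximise the penalized likelihood
        # over (b, beta, mu, log sigma_i2, log sigma_n2) at fixed tau
        r = np.random.default_rng(16)
        n = 150
        x = r.integers(0, 3, size=n).astype(float)
        y = 1.0 + 1.2 * x + r.normal(size=n)
        F = np.ones((n, 1))
        X = x[:, None]
        state = fit_pml(y, F, X, tol=1e-12, max_iter=2000)
        assert state.converged and state.active[0]

        def neg_lp(p):
            b, beta, mu, ls2, lsn2 = p
            cand = make_state([b], [beta], np.exp(lsn2), [mu], [np.exp(ls2)])
            return -penalized_loglik(cand, y, F, X)

        x0 = np.array([y.mean(), 1.0, 0.5, np.log(0.25), np.log(np.var(y))])
        res = optimize.minimize(neg_lp, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        b, beta, mu, ls2, lsn2 = res.x
        assert abs(state.beta[0] - beta) < 1e-4
        assert abs(state.mu[0] - mu) < 1e-4
        assert abs(state.sigma_i2[0] - np.exp(ls2)) < 1e-4
        assert abs(state.sigma_n2 - np.exp(lsn2)) < 1e-4


class TestLodScores:
    def test_zero_effect_marker_has_zero_lod(self):
        y, F, X = random_problem(17, t=2, effects=[1.0, 0.0])
        state = fit_pml(y, F, X)
        state.beta[1] = 0.0
        assert lrt_lod(state, 1, y, F, X) == 0.0

    def test_lr_to_lod_arithmetic(self):
        assert abs(13.8155 / (2.0 * np.log(10.0)) - 3.0) < 1e-4

    def test_lod_invariant_to_common_rescaling(self):
        r = np.random.default_rng(18)
        n = 100
        x = r.integers(0, 3, size=n).astype(float)
        y = 2.0 + 1.5 * x + r.normal(size=n)
        F = np.ones((n, 1))
        X = x[:, None]
        state = fit_pml(y, F, X)
        lod = lrt_lod(state, 0, y, F, X)
        alpha = 3.7
        scaled = make_state(state.b * alpha, state.beta * alpha,
                            state.sigma_n2 * alpha**2, state.mu * alpha,
                            state.sigma_i2 * alpha**2)
        assert abs(lrt_lod(scaled, 0, alpha * y, F, X) - lod) < 1e-9

    def test_select_markers_applies_both_thresholds(self):
        r = np.random.default_rng(19)
        n = 150
        X = r.integers(0, 3, size=(n, 3)).astype(float)
        y = 1.0 + X[:, 0] * 1.5 + r.normal(size=n)
        F = np.ones((n, 1))
        state = fit_pml(y, F, X)
        result = select_markers(state, y, F, X)
        assert 0 in result.selected
        assert np.all(result.lod >= 3.0)
        assert np.all(np.abs(result.effects) > 1e-4)
        assert result.std_errors.shape == result.selected.shape
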