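import numpy as np
import pytest
from scipy import integrate, special, stats

from ebeqtl.peb_mixture import (
    EStepState,
    TMixtureParams,
    apply_pi0_cap,
    cm_step1,
    cm_step2,
    e_step,
    ecme_fit,
    pi0_upper_bound,
    t_pdf,
)


def make_params(pi=(0.9, 0.07, 0.03), mu=(0, 4, -4), tau2=(1, 0.5, 0.5), nu=(10, 10, 10)):
    return TMixtureParams(np.array(pi, float), np.array(mu, float), np.array(tau2, float), np.array(nu, float))


def sample_mixture(params, n, rng):
    comp = rng.choice(3, size=n, p=params.pi)
    out = np.empty(n)
    for k in range(3):
        m = comp == k
        out[m] = stats.t.rvs(
            df=params.nu[k], loc=params.mu[k], scale=np.sqrt(params.tau2[k]),
            size=int(m.sum()), random_state=rng,
        )
    return out


class TestTPdf:
    def test_cauchy_center(self):
        assert t_pdf(0.0, 0.0, 1.0, 1.0) == pytest.approx(1 / np.pi, abs=1e-12)

    def test_gaussian_limit(self):
        assert t_pdf(0.0, 0.0, 1.0, 1e6) == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-6)

    @pytest.mark.parametrize("mu,tau2,nu", [(0, 1, 3), (4, 0.5, 10), (-2, 2, 5)])
    def test_integrates_to_one(self, mu, tau2, nu):
        left, _ = integrate.quad(lambda z: t_pdf(z, mu, tau2, nu), -np.inf, mu, limit=400)
        right, _ = integrate.quad(lambda z: t_pdf(z, mu, tau2, nu), mu, np.inf, limit=400)
        assert left + right == pytest.approx(1.0, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            t_pdf(0.0, 0.0, -1.0, 5.0)


class TestEStep:
    def test_single_active_component(self, rng):
        params = make_params(pi=(1, 0, 0))
        state = e_step(rng.standard_normal(30), params)
        np.testing.assert_allclose(state.xi[:, 0], 1.0)
        np.testing.assert_allclose(state.xi[:, 1:], 0.0)

    def test_weight_at_component_center(self):
        params = make_params()
        state = e_step(np.array([4.0]), params)  # z at mu_1
        assert state.u[0, 1] == pytest.approx((10 + 1) / 10, abs=1e-12)

    def test_matches_scalar_density_ratios(self, rng):
        """Responsibilities equal a from-scratch evaluation of
        pi_k f_k / sum_m pi_m f_m using scipy's t densities."""
        params = make_params(pi=(0.6, 0.25, 0.15), mu=(0, 2.5, -1.5), tau2=(1, 0.8, 1.7), nu=(7, 4, 12))
        z = rng.standard_normal(50) * 3
        state = e_step(z, params)
        np.testing.assert_allclose(state.xi.sum(axis=1), 1.0, atol=1e-12)
        dens = np.column_stack(
            [
                params.pi[k]
                * stats.t.pdf(z, df=params.nu[k], loc=params.mu[k], scale=np.sqrt(params.tau2[k]))
                for k in range(3)
            ]
        )
        np.testing.assert_allclose(state.xi, dens / dens.sum(axis=1, keepdims=True), atol=1e-12)
        np.testing.assert_allclose(state.loglik, np.log(dens.sum(axis=1)).sum(), rtol=1e-12)


class TestCMStep1:
    def test_empty_components_pruned(self, rng):
        params = make_params()
        z = rng.standard_normal(100)
        n = z.size
        state = EStepState(
            xi=np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)]),
            u=np.ones((n, 3)),
            loglik=0.0,
        )
        new = cm_step1(z, state, params)
        np.testing.assert_allclose(new.pi, [1, 0, 0])

    def test_gaussian_em_reduction(self, rng):
        """With unit weights, the location update is the responsibility-
        weighted mean and the scale update its mean squared deviation."""
        z = rng.standard_normal(200) + 2.0
        n = z.size
        xi = np.column_stack([np.full(n, 0.3), np.full(n, 0.7), np.zeros(n)])
        state = EStepState(xi=xi, u=np.ones((n, 3)), loglik=0.0)
        new = cm_step1(z, state, make_params())
        assert new.mu[1] == pytest.approx(z.mean(), abs=1e-12)
        assert new.tau2[1] == pytest.approx(((z - z.mean()) ** 2).mean(), abs=1e-12)

    def test_matches_direct_formulas(self, rng):
        params = make_params()
        z = rng.standard_normal(50) * 2
        state = e_step(z, params)
        new = cm_step1(z, state, params)
        for k in (1, 2):
            xu = state.xi[:, k] * state.u[:, k]
            mu_k = (xu * z).sum() / xu.sum()
            mu_k = max(mu_k, 1e-3) if k == 1 else min(mu_k, -1e-3)
            tau2_k = (xu * (z - mu_k) ** 2).sum() / state.xi[:, k].sum()
            assert new.mu[k] == pytest.approx(mu_k, abs=1e-12)
            assert new.tau2[k] == pytest.approx(tau2_k, abs=1e-12)
        np.testing.assert_allclose(new.pi, state.xi.mean(axis=0), atol=1e-12)
        assert new.pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestCMStep2:
    def test_unit_weights_hit_upper_bound(self, rng):
        """When every weight is 1 the df equation has no root below the
        upper bound (the Gaussian limit)."""
        params = make_params(pi=(0.0, 1.0, 0.0), mu=(0, 0.001, -1), nu=(10, 10, 10))
        z = np.full(100, 0.001)  # zero residuals => u = (nu+1)/nu ~ 1 only at huge nu
        new, _ = cm_step2(rng.standard_normal(100) * 0 + 0.001, params)
        assert new.nu[1] <= 200

    def test_recovers_df_of_single_t(self, rng):
        """Responsibilities from a pure t(0,1,5) sample drive the df update
        into the range a direct likelihood grid search finds."""
        z = stats.t.rvs(df=5, size=10_000, random_state=rng)
        params = make_params(pi=(0.0, 1.0, 0.0), mu=(0, 1e-3, -1), tau2=(1, 1, 1), nu=(10, 10, 10))
        for _ in range(40):  # iterate CM-step 2 with refreshed weights to a fixed point
            params, _ = cm_step2(z, params)
        assert 4.0 <= params.nu[1] <= 6.5
        grid = np.linspace(3, 9, 121)
        ll = [stats.t.logpdf(z, df=v, loc=1e-3).sum() for v in grid]
        assert abs(params.nu[1] - grid[int(np.argmax(ll))]) < 1.0

    def test_root_decreases_in_weight_statistic(self):
        """Brute-force scan: the estimating-equation root moves down as the
        data-dependent term grows more negative."""
        from ebeqtl.peb_mixture import _df_equation

        grid = np.linspace(1, 200, 4000)

        def root(c):
            vals = np.array([_df_equation(v, c) for v in grid])
            idx = np.nonzero(np.diff(np.sign(vals)))[0]
            return grid[idx[0]] if idx.size else (1.0 if vals[0] <= 0 else 200.0)

        roots = [root(c) for c in (-1.05, -1.1, -1.2, -1.4)]
        assert all(a >= b for a, b in zip(roots, roots[1:]))


class TestEcmeFit:
    TRUE = dict(pi=(0.9, 0.07, 0.03), mu=(0, 4, -4), tau2=(1, 0.5, 0.5), nu=(10, 10, 10))

    def test_parameter_recovery_across_seeds(self):
        """n = 10,000 draws from a known 3-component t mixture: pi within
        +/-0.02 and mu within +/-0.3 in at least 9 of 10 seeds."""
        truth = make_params(**self.TRUE)
        successes = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            z = sample_mixture(truth, 10_000, rng)
            fitted, trace = ecme_fit(z, nu0=10.0)
            assert np.all(np.diff(trace) >= -1e-8)
            ok = (
                np.all(np.abs(fitted.pi - truth.pi) <= 0.02)
                and abs(fitted.mu[1] - 4) <= 0.3
                and abs(fitted.mu[2] + 4) <= 0.3
                and np.all(np.abs(fitted.tau2 - truth.tau2) <= 0.3)
            )
            successes += ok
        assert successes >= 9

    def test_pure_null_keeps_pi0_high(self):
        for seed in range(5):
            rng = np.random.default_rng(2000 + seed)
            z = stats.t.rvs(df=10, size=5000, random_state=rng)
            fitted, _ = ecme_fit(z, nu0=10.0)
            assert fitted.pi[0] >= 0.97

    def test_positive_shifts_prune_negative_component(self):
        truth = make_params(pi=(0.95, 0.05, 0.0), mu=(0, 5, -1), nu=(30, 20, 10))
        for seed in range(3):
            rng = np.random.default_rng(3000 + seed)
            z = sample_mixture(truth, 10_000, rng)
            fitted, _ = ecme_fit(z, nu0=30.0)
            assert fitted.pi[2] < 0.01

    def test_pinned_null_constraints_hold(self, rng):
        z = sample_mixture(make_params(**self.TRUE), 5000, rng)
        fitted, _ = ecme_fit(z, nu0=8.5)
        assert fitted.mu[0] == 0.0 and fitted.tau2[0] == 1.0 and fitted.nu[0] == 8.5
        assert fitted.pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_limit_matches_independent_gaussian_em(self, rng):
        """With all dfs pinned at 1e6 the ECME estimates agree with an
        independently coded Gaussian-mixture EM (same null pinning) to 1e-3."""
        truth = make_params(nu=(1e6, 1e6, 1e6))
        z = sample_mixture(truth, 10_000, rng)
        fitted, _ = ecme_fit(z, nu0=1e6, nu_range=(1e6, 1e6), tol=1e-12, max_iter=3000)

        # oracle: plain Gaussian EM with component 0 pinned at N(0,1)
        pi = np.array([np.mean(np.abs(z) <= 2), np.mean(z > 2), np.mean(z < -2)])
        mu = np.array([0.0, z[z > 2].mean(), z[z < -2].mean()])
        var = np.array([1.0, z[z > 2].var(), z[z < -2].var()])
        for _ in range(3000):
            dens = np.column_stack(
                [pi[k] * stats.norm.pdf(z, mu[k], np.sqrt(var[k])) for k in range(3)]
            )
            resp = dens / dens.sum(axis=1, keepdims=True)
            old = pi.copy()
            pi = resp.mean(axis=0)
            for k in (1, 2):
                mu[k] = (resp[:, k] * z).sum() / resp[:, k].sum()
                var[k] = (resp[:, k] * (z - mu[k]) ** 2).sum() / resp[:, k].sum()
            if np.abs(pi - old).max() < 1e-12:
                break
        np.testing.assert_allclose(fitted.pi, pi, atol=1e-3)
        np.testing.assert_allclose(fitted.mu[1:], mu[1:], atol=1e-3)
        np.testing.assert_allclose(fitted.tau2[1:], var[1:], atol=1e-3)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ecme_fit(np.zeros(10), nu0=5.0)


class TestPi0Bound:
    def test_identical_densities_give_one(self, rng):
        z = stats.t.rvs(df=8, size=2000, random_state=rng)
        f0 = t_pdf(z, 0.0, 1.0, 8.0)
        assert pi0_upper_bound(z, 8.0, f0) == 1.0

    def test_bound_dominates_true_pi0(self, rng):
        """For a two-group mixture with the exact mixture density, the
        ratio at any z is pi0 + pi1 f1/f0 >= pi0."""
        params = make_params(pi=(0.9, 0.1, 0.0), mu=(0, 4, -1))
        z = sample_mixture(params, 4000, rng)
        from ebeqtl.peb_mixture import mixture_pdf

        bound = pi0_upper_bound(z, 10.0, mixture_pdf(z, params))
        assert bound >= 0.9 - 1e-9

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            pi0_upper_bound(np.array([]), 5.0, np.array([]))

    def test_cap_renormalizes(self, rng):
        params = make_params(pi=(0.9, 0.1, 0.0), mu=(0, 4, -1))
        z = sample_mixture(params, 4000, rng)
        capped = apply_pi0_cap(z, params)
        assert capped.pi.sum() == pytest.approx(1.0, abs=1e-12)
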