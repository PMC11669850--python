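import numpy as np
import pytest
from scipy import integrate, special, stats

from recurroc import DGPSpec, simulate_dataset
from recurroc.data_model import RecurrentData
from recurroc.frailty_em import (
    EMConfig,
    FrailtyFit,
    estep_frailty_logmean,
    estep_frailty_mean,
    fit_em,
    marginal_loglik,
    update_baseline,
    update_beta,
    update_theta,
)


def subject(sid, m, C, events, tau=5.0):
    return RecurrentData(sid, m, C, np.asarray(events, dtype=float), tau)


class TestEStep:
    def test_posterior_mean_closed_form(self):
        assert estep_frailty_mean(3, 0.5, 2.0) == pytest.approx(1.25)
        assert estep_frailty_mean(0, 0.7, 0.0) == pytest.approx(1.0)
        assert estep_frailty_mean(5, 0.0, 3.0) == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            estep_frailty_mean(-1, 0.5, 1.0)

    def test_posterior_logmean_digamma_values(self):
        assert estep_frailty_logmean(0, 1.0, 0.0) == pytest.approx(special.digamma(1))
        assert estep_frailty_logmean(1, 1.0, 0.0) == pytest.approx(special.digamma(2))

    def test_posterior_logmean_matches_numeric_integral(self):
        # gamma posterior for (n=2, theta=0.5, mu=3): shape 4, scale 0.2
        n_i, theta, mu = 2, 0.5, 3.0
        shape = 1.0 / theta + n_i
        scale = theta / (1.0 + theta * mu)
        num, _ = integrate.quad(
            lambda u: np.log(u) * stats.gamma.pdf(u, shape, scale=scale), 0, np.inf
        )
        assert estep_frailty_logmean(n_i, theta, mu) == pytest.approx(num, abs=1e-9)
        assert estep_frailty_logmean(n_i, theta, mu) == pytest.approx(
            special.digamma(4) + np.log(0.2)
        )

    def test_zero_theta_needs_poisson_branch(self):
        with pytest.raises(ValueError):
            estep_frailty_logmean(1, 0.0, 1.0)


class TestBaselineUpdate:
    def test_single_subject_breslow(self):
        data = [subject(1, 0.0, 5.0, [1.0, 2.0])]
        s, d = update_baseline(data, beta=0.0, frailty_means=[1.0])
        np.testing.assert_allclose(s, [1.0, 2.0])
        np.testing.assert_allclose(d, [1.0, 1.0])

    def test_risk_set_drops_censored_subject(self):
        data = [subject(1, 0.0, 5.0, [1.0]), subject(2, 0.0, 0.5, [])]
        _, d = update_baseline(data, beta=0.0, frailty_means=[1.0, 1.0])
        np.testing.assert_allclose(d, [1.0])

    def test_weighted_denominator(self):
        data = [subject(1, 0.0, 5.0, [2.0]), subject(2, 1.0, 5.0, [])]
        _, d = update_baseline(data, beta=np.log(2.0), frailty_means=[1.0, 1.0])
        np.testing.assert_allclose(d, [1.0 / 3.0])


class TestBetaUpdate:
    def test_degenerate_design_returns_init(self):
        data = [subject(1, 0.7, 5.0, [1.0]), subject(2, 0.7, 5.0, [2.0, 3.0])]
        s, d = update_baseline(data, 0.0, [1.0, 1.0])
        assert update_beta(data, [1.0, 1.0], (s, d), init=0.0) == 0.0

    def test_matches_grid_search_of_expected_loglik(self):
        # fixed baseline and frailty means: the solved score maximizes
        # sum_i [n_i beta m_i - u_i mu0(C_i) exp(beta m_i)]
        rng = np.random.default_rng(5)
        data = [
            subject(i, float(rng.normal()), 5.0, np.sort(rng.uniform(0, 5, rng.integers(0, 5))))
            for i in range(25)
        ]
        u = rng.uniform(0.5, 1.5, 25)
        s, d = update_baseline(data, 0.3, u)
        beta_hat = update_beta(data, u, (s, d), init=0.0)

        m = np.array([x.marker for x in data])
        counts = np.array([x.n_events for x in data])
        mu0C = np.full(25, d.sum())  # complete follow-up: mu0(C_i)=mu0(tau)
        grid = np.linspace(-2, 2, 20001)
        obj = (counts * m)[None, :] * grid[:, None] - (u * mu0C)[None, :] * np.exp(
            grid[:, None] * m[None, :]
        )
        beta_grid = grid[np.argmax(obj.sum(axis=1))]
        assert beta_hat == pytest.approx(beta_grid, abs=2e-4)


class TestThetaUpdate:
    def test_no_heterogeneity_collapses_to_zero(self):
        n = 50
        assert update_theta(np.ones(n), np.ones(n), np.zeros(n)) == 0.0

    def test_returned_value_beats_grid(self):
        rng = np.random.default_rng(9)
        Eu = rng.uniform(0.3, 2.0, 40)
        Elog = np.log(Eu) - rng.uniform(0.05, 0.3, 40)  # Jensen-consistent
        theta_hat = update_theta(None, Eu, Elog, theta_floor=1e-8)
        from recurroc.frailty_em import _theta_objective

        best = _theta_objective(theta_hat, Eu, Elog)
        for theta in np.exp(np.linspace(np.log(1e-5), np.log(40), 300)):
            assert _theta_objective(theta, Eu, Elog) <= best + 1e-9

    def test_infinite_floor_forces_poisson(self):
        assert update_theta(None, np.ones(5) * 2, np.ones(5), theta_floor=np.inf) == 0.0


class TestFitEM:
    def test_no_events_rejected(self):
        data = [subject(1, 0.0, 5.0, []), subject(2, 1.0, 5.0, [])]
        with pytest.raises(ValueError):
            fit_em(data)

    def test_single_subject_composition(self):
        data = [subject(1, 0.0, 5.0, [1.0, 2.0])]
        fit = fit_em(data, EMConfig(theta_floor=np.inf))
        s, d = update_baseline(data, fit.beta, [1.0])
        np.testing.assert_allclose(fit.baseline_increments, d)
        assert fit.posterior_frailty_means[0] == pytest.approx(
            estep_frailty_mean(2, fit.theta, fit.mu0_at(5.0))
        )

    def test_em_ascent_on_seeded_datasets(self, small_datasets):
        for ds in small_datasets:
            fit = fit_em(ds.observed)
            diffs = np.diff(fit.loglik_path)
            assert diffs.size == 0 or diffs.min() > -1e-8

    def test_posterior_means_average_to_one(self, gamma_fit):
        assert abs(gamma_fit.posterior_frailty_means.mean() - 1.0) < 0.02

    def test_poisson_reduction_matches_glm(self, risk):
        # complete follow-up: profile beta == Poisson GLM slope of counts on marker
        import statsmodels.api as sm

        ds = simulate_dataset(DGPSpec(n=400, beta1=0.5, theta=0.0, seed=21))
        fit = fit_em(ds.observed, EMConfig(theta_floor=np.inf))
        assert fit.theta == 0.0
        m = ds.markers
        counts = np.array([d.n_events for d in ds.observed])
        glm = sm.GLM(counts, sm.add_constant(m), family=sm.families.Poisson()).fit()
        assert fit.beta == pytest.approx(glm.params[1], abs=1e-6)
        # and mu0(tau) matches the GLM intercept rate
        assert fit.mu0_at(5.0) == pytest.approx(np.exp(glm.params[0]), rel=1e-6)

    def test_parameter_recovery_seeded(self):
        ds = simulate_dataset(DGPSpec(n=2000, beta1=0.5, theta=1.0, seed=33))
        fit = fit_em(ds.observed)
        assert fit.converged
        assert fit.beta == pytest.approx(0.5, abs=0.10)
        assert fit.theta == pytest.approx(1.0, abs=0.15)

    def test_theta_shrinks_under_poisson_truth(self):
        ds = simulate_dataset(DGPSpec(n=2000, beta1=0.5, theta=0.0, seed=34))
        fit = fit_em(ds.observed)
        assert fit.theta < 0.05

    def test_loglik_invariant_to_marker_shift(self, small_datasets):
        import dataclasses

        ds = small_datasets[0]
        fit = fit_em(ds.observed)
        shifted = [dataclasses.replace(d, marker=d.marker + 2.0) for d in ds.observed]
        fit2 = fit_em(shifted)
        assert fit2.marginal_loglik == pytest.approx(fit.marginal_loglik, abs=1e-5)
        assert fit2.beta == pytest.approx(fit.beta, abs=1e-5)


class TestMarginalLoglik:
    def test_poisson_limit_closed_form(self, small_datasets):
        ds = small_datasets[2]
        fit = fit_em(ds.observed, EMConfig(theta_floor=np.inf))
        # direct Poisson likelihood: sum_j log(dmu0 e^{beta m}) - mu_i(C_i)
        ll = 0.0
        for d in ds.observed:
            mu_C = fit.mu0_at(d.censor_time) * np.exp(fit.beta * d.marker)
            jumps = np.searchsorted(fit.baseline_times, d.event_times)
            ll += float(
                np.sum(np.log(fit.baseline_increments[jumps]) + fit.beta * d.marker)
            ) - mu_C
        assert marginal_loglik(fit, ds.observed) == pytest.approx(ll, abs=1e-8)

    def test_json_round_trip(self, gamma_fit, gamma_dataset):
        back = FrailtyFit.from_json(gamma_fit.to_json())
        assert back.beta == gamma_fit.beta
        assert back.theta == gamma_fit.theta
        np.testing.assert_array_equal(back.baseline_times, gamma_fit.baseline_times)
        np.testing.assert_array_equal(back.baseline_increments, gamma_fit.baseline_increments)
        assert marginal_loglik(back, gamma_dataset.observed) == pytest.approx(
            gamma_fit.marginal_loglik, abs=1e-6
        )
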