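"""Tests for the random-walk Metropolis sampler and posterior summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from addint.bayes import (
    PriorSpec,
    log_posterior,
    posterior_measures,
    psrf,
    random_walk_metropolis,
    sample_posterior,
)
from addint.bootstrap import empirical_quantile
from addint.model_fit import Measure, SubjectData, fit_logistic_mle
from addint.simulate import builtin_scenarios, draw_sample


def _toy_data():
    return SubjectData(
        outcome=np.array([1, 0, 1, 1, 0]),
        factor_a=np.array([1, 0, 1, 0, 1]),
        factor_b=np.array([0, 0, 1, 1, 1]),
    )


class TestLogPosterior:
    def test_zero_coefficients_single_subject(self):
        data = SubjectData(outcome=[1], factor_a=[0], factor_b=[0])
        prior = PriorSpec()
        got = log_posterior(np.zeros(4), data, prior)
        assert got == pytest.approx(prior.logpdf(np.zeros(4)) + math.log(0.5))

    def test_difference_matches_brute_force_product(self):
        """Log-posterior differences equal the direct product-form likelihood
        ratio computed subject by subject."""
        data = _toy_data()
        prior = PriorSpec(sd=5.0)
        t1 = np.array([0.2, -0.4, 0.9, 1.4])
        t2 = np.array([-1.0, 0.3, 0.1, -0.2])

        def brute(theta):
            x = data.design_matrix()
            eta = x @ theta
            h = 1 / (1 + np.exp(-eta))
            lik = np.prod(h**data.outcome * (1 - h) ** (1 - data.outcome))
            pri = np.prod(stats.norm.pdf(theta, 0, 5.0))
            return math.log(lik * pri)

        got = log_posterior(t1, data, prior) - log_posterior(t2, data, prior)
        assert got == pytest.approx(brute(t1) - brute(t2), rel=1e-9)

    def test_aggregated_and_subject_level_paths_agree(self, oral_subjects):
        """The 8-cell sufficient-statistic likelihood equals the subject-level
        Bernoulli likelihood."""
        with_conf = SubjectData(
            outcome=oral_subjects.outcome,
            factor_a=oral_subjects.factor_a,
            factor_b=oral_subjects.factor_b,
            confounders=np.zeros((oral_subjects.n, 1)),
        )
        theta4 = np.array([-1.9, 1.1, 1.2, 2.2])
        theta5 = np.append(theta4, 0.0)
        prior = PriorSpec()
        diff = log_posterior(theta4, oral_subjects, prior) - log_posterior(
            theta5, with_conf, prior
        )
        # only the prior of the extra (zero) confounder coefficient differs
        assert diff == pytest.approx(
            -stats.norm.logpdf(0.0, 0.0, 10.0), rel=1e-9
        )

    def test_diffuse_prior_mode_approaches_mle(self, oral_subjects):
        from scipy.optimize import minimize

        mle = fit_logistic_mle(oral_subjects).params()
        prior = PriorSpec(sd=1e4)
        res = minimize(
            lambda t: -log_posterior(t, oral_subjects, prior),
            np.zeros(4),
            method="BFGS",
        )
        assert res.x == pytest.approx(mle, abs=1e-3)

    def test_nonfinite_theta_has_zero_density(self):
        assert log_posterior(np.array([np.inf, 0, 0, 0]), _toy_data()) == -math.inf


class TestSampler:
    def test_deterministic_given_seed(self, oral_subjects):
        s1 = sample_posterior(oral_subjects, n_iter=2000, n_burnin=1000, seed=5)
        s2 = sample_posterior(oral_subjects, n_iter=2000, n_burnin=1000, seed=5)
        assert all(np.array_equal(a, b) for a, b in zip(s1.chains, s2.chains))
        assert s1.acceptance_rates == s2.acceptance_rates

    def test_retained_draw_count_and_acceptance_rate(self, oral_subjects):
        s = sample_posterior(
            oral_subjects, n_iter=3000, n_burnin=1200, n_chains=2, seed=8
        )
        for chain in s.chains:
            assert chain.shape == (1800, 4)
        for rate in s.acceptance_rates:
            assert 0.05 < rate < 0.8

    def test_matches_quadrature_on_one_parameter_model(self):
        """Posterior mean from Metropolis agrees with exact 1-D quadrature."""
        rng = np.random.default_rng(4)
        x = np.array([1.0, -1.0, 1.0, 1.0, -1.0, 1.0, -1.0, 1.0, 1.0, -1.0])
        y = np.array([1, 0, 1, 1, 0, 0, 1, 1, 1, 0])

        def logpost(theta):
            eta = theta[0] * x
            ll = float(y @ eta - np.logaddexp(0, eta).sum())
            return ll + float(stats.norm.logpdf(theta[0], 0, 10))

        grid = np.linspace(-15, 15, 4001)
        dens = np.exp([logpost(np.array([g])) for g in grid])
        dens /= np.trapezoid(dens, grid)
        exact_mean = np.trapezoid(grid * dens, grid)

        draws, rate = random_walk_metropolis(
            logpost, np.zeros(1), np.array([[1.0]]), 30_000, 5_000, rng
        )
        import arviz as az

        ess = float(az.ess(az.convert_to_dataset(draws[None, :, 0])).x)
        mcse = draws[:, 0].std() / math.sqrt(ess)
        assert abs(draws[:, 0].mean() - exact_mean) < 3 * mcse + 1e-3

    def test_posterior_median_near_mle_for_moderate_data(self):
        scenario = [s for s in builtin_scenarios(1000, 1000) if s.id == "A2"][0]
        data = draw_sample(scenario, seed=99)
        mle = fit_logistic_mle(data).params()
        s = sample_posterior(data, n_iter=8000, n_burnin=4000, n_chains=2, seed=17)
        medians = np.median(s.pooled(), axis=0)
        assert medians == pytest.approx(mle, abs=0.05)

    def test_psrf_recorded_and_near_one(self, oral_subjects):
        s = sample_posterior(
            oral_subjects, n_iter=6000, n_burnin=3000, n_chains=2, seed=23
        )
        assert s.psrf is not None
        assert (s.psrf < 1.1).all()


class TestPsrf:
    def test_identical_chains(self):
        c = np.random.default_rng(0).normal(size=(500, 2))
        r = psrf([c, c.copy()])
        assert np.all(r <= 1.0) and np.all(r > 0.99)

    def test_independent_normal_chains_converged(self):
        rng = np.random.default_rng(1)
        chains = [rng.normal(size=(5000, 1)) for _ in range(3)]
        assert psrf(chains).max() < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(0, 1, size=(500, 1)), rng.normal(10, 1, size=(500, 1))]
        assert psrf(chains).min() > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="two chains"):
            psrf([np.zeros((100, 2))])


class TestPosteriorMeasures:
    def test_degenerate_sample_gives_zero_width_interval(self):
        from addint.bayes import PosteriorSample

        draw = np.array([0.0, math.log(2), math.log(3), math.log(12)])
        sample = PosteriorSample(
            chains=[np.tile(draw, (200, 1))],
            param_names=("beta0", "beta1", "beta2", "beta3"),
            n_iter=400, n_burnin=200, seed=0, acceptance_rates=[0.3],
        )
        est = posterior_measures(sample)
        assert est["RERI"].point == pytest.approx(12 - 2 - 3 + 1)
        assert est["RERI"].lower == est["RERI"].upper == est["RERI"].point
        assert est["S"].point == pytest.approx(11 / 3)

    def test_quantiles_match_independent_sort(self, oral_subjects):
        from addint.measures import measures_from_draws

        s = sample_posterior(oral_subjects, n_iter=4000, n_burnin=2000, seed=31)
        est = posterior_measures(s, include_nonrisk_draws=True)
        mapped = measures_from_draws(s.pooled()[:, 1:4])
        reri = np.sort(mapped["RERI"])
        n = len(reri)
        assert est["RERI"].lower == reri[math.ceil(0.025 * n) - 1]
        assert est["RERI"].upper == reri[math.ceil(0.975 * n) - 1]
        assert est["RERI"].lower <= est["RERI"].point <= est["RERI"].upper

    def test_recode_invariant_when_all_factors_clearly_risky(self):
        scenario = [s for s in builtin_scenarios() if s.id == "A1"][0]
        data = draw_sample(scenario, seed=3)
        s = sample_posterior(data, n_iter=4000, n_burnin=2000, seed=7)
        plain = posterior_measures(s, recode=False)
        recoded = posterior_measures(s, recode=True)
        for m in Measure:
            assert plain[m.value].point == recoded[m.value].point
            assert plain[m.value].lower == recoded[m.value].lower
            assert plain[m.value].upper == recoded[m.value].upper

    def test_draw_policies_are_nested(self, oral_subjects):
        """Full-posterior S interval must be at least as wide as the
        risk-coded default, and the excluded fraction is reported."""
        s = sample_posterior(oral_subjects, seed=41)
        strict = posterior_measures(s)
        full = posterior_measures(s, include_nonrisk_draws=True)
        assert full["S"].upper >= strict["S"].upper
        assert 0 < strict["RERI"].diagnostics["fraction_undefined"] < 0.5

    def test_hpd_no_wider_than_equal_tail(self, oral_subjects):
        s = sample_posterior(oral_subjects, n_iter=6000, n_burnin=3000, seed=43)
        et = posterior_measures(s)
        hp = posterior_measures(s, hpd=True)
        for m in ("RERI", "AP"):
            assert (hp[m].upper - hp[m].lower) <= (et[m].upper - et[m].lower) * 1.001
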