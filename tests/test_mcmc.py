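import numpy as np
import pytest
from scipy.stats import beta as beta_dist, kstest

import underdx as u
from underdx.mcmc import (McmcConfig, ModelParams, gibbs_update_s,
                          gibbs_update_theta, latent_posterior_prob,
                          s_posterior, sample_posterior, summarize_posterior,
                          theta_posterior, update_coefficients)
from underdx.naive import DesignMatrix
from underdx.priors import BetaPrior, NormalPrior, ScenarioPrior


class TestLatentPosteriorProb:
    def test_symmetric_case(self):
        assert latent_posterior_prob(0.5, 0.0, 0.3, 0.3) == pytest.approx(0.5)

    def test_low_prevalence_arithmetic(self):
        # theta(1-s) = 0.0007 against (1-theta) = 0.998 with equal likelihoods
        p = latent_posterior_prob(0.002, 0.65, 0.4, 0.4)
        assert p == pytest.approx(0.0007 / (0.0007 + 0.998), rel=1e-9)
        assert p == pytest.approx(7.009e-4, rel=1e-3)

    def test_informative_outcome(self):
        assert latent_posterior_prob(0.5, 0.5, 0.8, 0.2) == pytest.approx(2 / 3)

    def test_vectorized(self):
        out = latent_posterior_prob(0.5, 0.5, np.array([0.8, 0.2]),
                                    np.array([0.2, 0.8]))
        # 0.25*0.8/(0.25*0.8 + 0.5*0.2) and 0.25*0.2/(0.25*0.2 + 0.5*0.8)
        assert out == pytest.approx([2 / 3, 1 / 9])


class TestConjugateUpdates:
    def test_theta_posterior_counts(self):
        prior = BetaPrior(1, 499)
        d = np.zeros(1000)
        d[:2] = 1
        post = theta_posterior(d, prior)
        assert (post.alpha, post.beta) == (3.0, 1497.0)
        empty = theta_posterior(np.zeros(50), prior)
        assert (empty.alpha, empty.beta) == (1.0, 549.0)

    def test_s_posterior_counts_only_true_cases(self):
        prior = BetaPrior(19.5, 10.5)
        d = np.zeros(100, dtype=int)
        d[:13] = 1
        r = np.zeros(100, dtype=int)
        r[:9] = 1
        post = s_posterior(d, r, prior)
        assert (post.alpha, post.beta) == (28.5, 14.5)
        # zero true cases: posterior equals prior
        post0 = s_posterior(np.zeros(100), np.zeros(100), prior)
        assert (post0.alpha, post0.beta) == (prior.alpha, prior.beta)

    def test_inconsistent_latent_state_rejected(self):
        with pytest.raises(RuntimeError, match="specificity"):
            s_posterior(np.array([0, 1]), np.array([1, 1]), BetaPrior(1, 1))

    def test_theta_draws_match_closed_form_mean(self):
        rng = np.random.default_rng(0)
        d = np.zeros(500)
        d[:20] = 1
        prior = BetaPrior(2, 30)
        post = theta_posterior(d, prior)
        draws = np.array([gibbs_update_theta(d, prior, rng) for _ in range(10_000)])
        sd = np.sqrt(post.alpha * post.beta / ((post.ess ** 2) * (post.ess + 1)))
        assert abs(draws.mean() - post.mean) < 3 * sd / np.sqrt(10_000)

    def test_s_draws_match_closed_form_distribution(self):
        rng = np.random.default_rng(1)
        d = np.zeros(200, dtype=int)
        d[:40] = 1
        r = np.zeros(200, dtype=int)
        r[:25] = 1
        prior = BetaPrior(19.5, 10.5)
        post = s_posterior(d, r, prior)
        draws = np.array([gibbs_update_s(d, r, prior, rng) for _ in range(10_000)])
        res = kstest(draws, lambda x: beta_dist.cdf(x, post.alpha, post.beta))
        assert res.pvalue > 0.001


class TestCoefficientUpdate:
    def empty_design(self) -> DesignMatrix:
        return DesignMatrix(np.empty(0), np.empty((0, 10)))

    def params(self) -> ModelParams:
        return ModelParams(beta0=-3.0, beta1=0.0, beta=np.zeros(9),
                           theta=0.01, s=0.7)

    def test_zero_scale_proposal_always_accepted_and_identity(self):
        """A proposal equal to the current state has MH ratio 1: the chain
        stays put without rejecting."""
        rng = np.random.default_rng(3)
        sc = ScenarioPrior("t", BetaPrior(1, 99), BetaPrior(21, 9))
        cur = self.params()
        new = update_coefficients(self.empty_design(), np.empty(0), sc, cur,
                                  rng, scales=0.0)
        assert new.beta0 == cur.beta0 and new.beta1 == cur.beta1
        assert (new.beta == cur.beta).all()

    def test_prior_recovery_without_data(self):
        """With no observations the MH kernel targets the prior: long-run
        draws match the normal prior's mean and variance within MC error."""
        rng = np.random.default_rng(4)
        sc = ScenarioPrior("t", BetaPrior(1, 99), BetaPrior(21, 9),
                           intercept_prior=NormalPrior(1.5, 4.0),
                           coefficient_prior=NormalPrior(0.0, 4.0))
        design = self.empty_design()
        cur = ModelParams(beta0=1.5, beta1=0.0, beta=np.zeros(9),
                          theta=0.01, s=0.7)
        draws = np.empty(12_000)
        for i in range(draws.size):
            cur = update_coefficients(design, np.empty(0), sc, cur, rng, scales=3.0)
            draws[i] = cur.beta0
        draws = draws[2_000:]
        assert draws.mean() == pytest.approx(1.5, abs=0.15)
        assert draws.var() == pytest.approx(4.0, rel=0.15)

    def test_nonconformable_latent_rejected(self):
        rng = np.random.default_rng(0)
        sc = ScenarioPrior("t", BetaPrior(1, 99), BetaPrior(21, 9))
        with pytest.raises(ValueError, match="conformable"):
            update_coefficients(self.empty_design(), np.ones(3), sc,
                                self.params(), rng)


class TestSamplePosterior:
    def scenario(self) -> ScenarioPrior:
        return ScenarioPrior("test", BetaPrior(2, 38), BetaPrior(21, 9))

    def test_identical_seeds_identical_draws(self, tiny_cohort):
        cfg = McmcConfig(n_chains=2, burn_in=50, n_samples=200, seed=7)
        a = sample_posterior(tiny_cohort, self.scenario(), cfg)
        b = sample_posterior(tiny_cohort, self.scenario(), cfg)
        np.testing.assert_array_equal(a.beta1, b.beta1)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.latent_count, b.latent_count)

    def test_perfect_specificity_invariant(self, small_cohort):
        """Reported cases keep D = 1 at every retained iteration; latent cases
        are counted only among the unreported."""
        cfg = McmcConfig(n_chains=1, burn_in=100, n_samples=400, seed=2,
                         store_latent=True)
        draws = sample_posterior(small_cohort, self.scenario(), cfg)
        reported = (small_cohort.reported_smi == "schizophrenia").to_numpy()
        assert (draws.latent[:, :, reported] == 1).all()
        assert (draws.latent_count >= 0).all()
        np.testing.assert_array_equal(
            draws.latent[:, :, ~reported].sum(axis=2), draws.latent_count)

    def test_acceptance_rates_in_tuned_band(self, small_cohort):
        cfg = McmcConfig(n_chains=1, burn_in=2_000, n_samples=1_500, seed=6)
        draws = sample_posterior(small_cohort, self.scenario(), cfg)
        assert ((draws.accept_rate > 0.15) & (draws.accept_rate < 0.5)).all()

    def test_latent_count_monotone_in_prior_underdiagnosis(self, small_cohort):
        """More prior underreporting (higher lambda mean) must not decrease the
        posterior expected number of hidden true cases."""
        means = []
        for s_mean in (0.87, 0.76, 0.65):  # lambda means 0.13, 0.24, 0.35
            sc = ScenarioPrior(f"s{s_mean}", u.elicit_prevalence_prior(0.05),
                               u.elicit_sensitivity_prior(s_mean, 30))
            d = sample_posterior(small_cohort, sc,
                                 McmcConfig(n_chains=1, burn_in=300,
                                            n_samples=1_500, seed=9))
            means.append(d.pooled("latent_count").mean())
        assert means[0] < means[1] < means[2]

    def test_invalid_config_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            sample_posterior(tiny_cohort, self.scenario(),
                             McmcConfig(n_chains=0))


class TestSummarizePosterior:
    def constant_draws(self, value: float) -> u.PosteriorDraws:
        k = 50
        return u.PosteriorDraws(
            beta0=np.full((1, k), -3.0), beta1=np.full((1, k), value),
            beta=np.zeros((1, k, 9)), theta=np.full((1, k), 0.01),
            s=np.full((1, k), 0.7), latent_count=np.zeros((1, k), dtype=int),
            coef_names=["bipolar", "ptsd", "mdd", "age_decades", "female",
                        "black", "other_race", "hispanic", "selim"])

    def test_constant_draws_give_point_interval(self):
        table = summarize_posterior(self.constant_draws(np.log(2.0)))
        row = table.set_index("term").loc["schizophrenia"]
        assert row.or_ == pytest.approx(2.0)
        assert row.ci_low == pytest.approx(2.0) and row.ci_high == pytest.approx(2.0)
        assert table.set_index("term").loc["lambda", "estimate"] == pytest.approx(0.3)

    def test_hand_computed_or_summaries(self):
        d = self.constant_draws(0.0)
        d.beta1 = np.log(np.array([[1.0, 2.0, 4.0]]))
        d.beta0 = d.beta0[:, :3]
        d.beta = d.beta[:, :3]
        d.theta, d.s, d.latent_count = d.theta[:, :3], d.s[:, :3], d.latent_count[:, :3]
        table = summarize_posterior(d).set_index("term")
        assert table.loc["schizophrenia", "or_"] == pytest.approx(7 / 3)
        assert table.loc["schizophrenia", "ci_low"] == pytest.approx(
            np.percentile([1.0, 2.0, 4.0], 2.5))

    def test_interval_nesting(self, tiny_cohort):
        cfg = McmcConfig(n_chains=1, burn_in=100, n_samples=500, seed=5)
        sc = ScenarioPrior("t", BetaPrior(2, 38), BetaPrior(21, 9))
        draws = sample_posterior(tiny_cohort, sc, cfg)
        wide = summarize_posterior(draws, level=0.95).set_index("term")
        narrow = summarize_posterior(draws, level=0.5).set_index("term")
        for term in ("schizophrenia", "selim", "theta"):
            assert wide.loc[term, "ci_low"] <= narrow.loc[term, "ci_low"]
            assert narrow.loc[term, "ci_high"] <= wide.loc[term, "ci_high"]
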