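"""Closed-form conjugate inference checked against independent oracles:
numerical quadrature of the unnormalized posterior, Monte-Carlo draws from
the posterior, and direct maximization of the exponential likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from adaptrial import (
    GammaParams,
    ImproperPosteriorError,
    SufficientStats,
    SurvivalRecord,
    efs_hazard_threshold,
    posterior_mean_var,
    posterior_tail_prob,
    predictive_survival,
    predictive_survival_sd,
    prior_from_mean_sd,
    prob_efs_meets_target,
    sufficient_stats,
    update_posterior,
)


def rec(fup, event, enroll=0.0, pid="p"):
    return SurvivalRecord(pid, enroll, fup, event)


class TestSufficientStats:
    @pytest.mark.parametrize(
        "records, expected",
        [
            ([rec(12.0, 1), rec(24.0, 0)], (1, 3.0)),
            ([], (0, 0.0)),
            ([rec(6.0, 1) for _ in range(100)], (100, 50.0)),
        ],
    )
    def test_reduction(self, records, expected):
        st_ = sufficient_stats(records)
        assert (st_.n_events, st_.total_exposure) == pytest.approx(expected)

    def test_additivity(self):
        a = [rec(10.0, 1), rec(30.0, 0)]
        b = [rec(5.0, 1), rec(7.0, 1), rec(60.0, 0)]
        assert sufficient_stats(a) + sufficient_stats(b) == sufficient_stats(a + b)

    def test_negative_followup_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("x", 0.0, -1.0, 0)


class TestPosteriorUpdate:
    def test_printed_update_rule(self):
        post = update_posterior(GammaParams(1, 1), SufficientStats(3, 20.0))
        assert (post.shape, post.rate) == (4, 21.0)

    def test_identity_on_empty_data(self):
        post = update_posterior(GammaParams(2, 10), SufficientStats(0, 0.0))
        assert (post.shape, post.rate) == (2, 10)

    def test_jeffreys_posterior_mean_is_mle(self):
        """With the 1/lam prior the posterior mean must equal the maximizer
        of the exponential likelihood, found here numerically."""
        records = [rec(12.0, 1), rec(18.0, 1), rec(30.0, 0), rec(24.0, 1),
                   rec(36.0, 0), rec(48.0, 1), rec(60.0, 1)]
        stats = sufficient_stats(records)
        post = update_posterior(GammaParams.jeffreys(), stats)
        mean, _ = posterior_mean_var(post)
        assert mean == pytest.approx(stats.n_events / stats.total_exposure)

        def negloglik(lam):
            years = [(r.followup_time / 12.0, r.event) for r in records]
            return -sum(d * math.log(lam) - lam * t for t, d in years)

        mle = minimize_scalar(negloglik, bounds=(1e-4, 5.0), method="bounded").x
        assert mean == pytest.approx(mle, rel=1e-5)

    def test_jeffreys_without_events_is_improper(self):
        with pytest.raises(ImproperPosteriorError):
            update_posterior(GammaParams.jeffreys(), SufficientStats(0, 10.0))

    def test_conjugacy_matches_quadrature(self):
        """Closed-form posterior density equals the normalized product of the
        exponential likelihood and the Gamma prior on a hazard grid."""
        prior = GammaParams(2.0, 15.0)
        records = [rec(12.0, 1), rec(30.0, 0), rec(20.0, 1), rec(48.0, 0)]
        stats = sufficient_stats(records)
        post = update_posterior(prior, stats)

        def unnorm(lam):
            like = 1.0
            for r in records:
                t = r.followup_time / 12.0
                like *= (lam * math.exp(-lam * t)) if r.event else math.exp(-lam * t)
            return like * gamma_dist.pdf(lam, a=prior.shape, scale=1 / prior.rate)

        Z, _ = quad(unnorm, 0, np.inf)
        grid = np.linspace(1e-4, 1.0, 400)
        numeric = np.array([unnorm(l) / Z for l in grid])
        closed = gamma_dist.pdf(grid, a=post.shape, scale=1 / post.rate)
        assert np.max(np.abs(numeric - closed)) < 1e-6


class TestMoments:
    @pytest.mark.parametrize(
        "shape, rate, mean, var",
        [(4.0, 21.0, 4 / 21, 4 / 441), (1.0, 1.0, 1.0, 1.0), (6.25, 250.0, 0.025, 1e-4)],
    )
    def test_mean_var(self, shape, rate, mean, var):
        assert posterior_mean_var(GammaParams(shape, rate)) == pytest.approx((mean, var))

    @pytest.mark.parametrize(
        "mean, sd, shape, rate",
        [(0.025, 0.01, 6.25, 250.0), (0.035, 0.02, 3.0625, 87.5)],
    )
    def test_moment_matching(self, mean, sd, shape, rate):
        p = prior_from_mean_sd(mean, sd)
        assert (p.shape, p.rate) == pytest.approx((shape, rate))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(mean=st.floats(1e-3, 1.0), sd=st.floats(1e-3, 0.5))
    def test_moment_matching_round_trip(self, mean, sd):
        m, v = posterior_mean_var(prior_from_mean_sd(mean, sd))
        assert m == pytest.approx(mean, rel=1e-12)
        assert v == pytest.approx(sd * sd, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            prior_from_mean_sd(0.0, 0.01)
        with pytest.raises(ValueError):
            prior_from_mean_sd(0.025, -1.0)


class TestPredictiveSurvival:
    def test_trivial_values(self):
        assert predictive_survival(GammaParams(3.7, 9.2), 0.0) == 1.0
        assert predictive_survival(GammaParams(1, 1), 1.0) == pytest.approx(0.5)
        assert predictive_survival_sd(GammaParams(1, 1), 1.0) == pytest.approx(
            math.sqrt(1 / 12), rel=1e-12
        )
        assert predictive_survival_sd(GammaParams(4, 21), 0.0) == 0.0

    def test_against_monte_carlo(self):
        """Closed forms for E[exp(-tau lam)] and its SD vs 1e6 posterior draws."""
        rng = np.random.default_rng(7)
        for shape, rate, tau in [(4.0, 21.0, 2.0), (6.25, 250.0, 2.0), (8.25, 430.0, 2.0)]:
            draws = rng.gamma(shape, 1.0 / rate, size=1_000_000)
            surv = np.exp(-tau * draws)
            p = GammaParams(shape, rate)
            se_mean = surv.std() / 1000.0
            assert abs(predictive_survival(p, tau) - surv.mean()) < 3 * se_mean
            sd = predictive_survival_sd(p, tau)
            se_sd = surv.std() / math.sqrt(2 * (len(surv) - 1))
            assert abs(sd - surv.std()) < 3 * se_sd

    def test_monotone_in_horizon_and_rate(self):
        taus = np.linspace(0.1, 10.0, 25)
        vals = [predictive_survival(GammaParams(3.0, 40.0), t) for t in taus]
        assert np.all(np.diff(vals) < 0)
        rates = np.linspace(5.0, 400.0, 25)
        vals = [predictive_survival(GammaParams(3.0, r), 2.0) for r in rates]
        assert np.all(np.diff(vals) > 0)

    def test_improper_rejected(self):
        with pytest.raises(ImproperPosteriorError):
            predictive_survival(GammaParams.jeffreys(), 2.0)


class TestTailProbabilities:
    def test_trivial_values(self):
        assert posterior_tail_prob(GammaParams(2, 3), 0.0) == 1.0
        assert posterior_tail_prob(GammaParams(1, 1), math.log(2)) == pytest.approx(0.5)

    def test_against_quadrature(self):
        p = GammaParams(4.0, 21.0)
        num, _ = quad(lambda l: gamma_dist.pdf(l, a=4, scale=1 / 21.0), 0.19, np.inf)
        assert abs(posterior_tail_prob(p, 0.19) - num) < 1e-8

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(shape=st.floats(0.1, 50), rate=st.floats(0.1, 500), r=st.floats(0, 2))
    def test_normalization(self, shape, rate, r):
        p = GammaParams(shape, rate)
        total = posterior_tail_prob(p, r, "at-or-above") + posterior_tail_prob(p, r, "below")
        assert total == pytest.approx(1.0, abs=1e-12)


class TestEfsTarget:
    def test_exponential_median_case(self):
        # threshold lambda0 = ln 2 makes the event a posterior median split
        efs0 = math.exp(-2 * math.log(2))
        assert prob_efs_meets_target(GammaParams(1, 1), efs0, 2.0) == pytest.approx(0.5)

    def test_loose_target_approaches_one(self):
        assert prob_efs_meets_target(GammaParams(4, 21), 1e-12, 2.0) > 0.999999

    def test_against_monte_carlo_frequency(self):
        p = GammaParams(6.25 + 2, 250.0 + 180.0)
        rng = np.random.default_rng(11)
        draws = rng.gamma(p.shape, 1.0 / p.rate, size=1_000_000)
        freq = float(np.mean(np.exp(-2 * draws) >= 0.92))
        se = math.sqrt(freq * (1 - freq) / 1e6)
        assert abs(prob_efs_meets_target(p, 0.92, 2.0) - freq) < 3 * se

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            prob_efs_meets_target(GammaParams(1, 1), 1.5, 2.0)
        with pytest.raises(ValueError):
            efs_hazard_threshold(0.92, 0.0)
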