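"""Tests for Bayesian JND estimation, summaries, and WAIC."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import truncnorm

from metabosense.inference import (
    McmcSettings,
    PriorSpec,
    cohort_waic,
    compare_models,
    compute_waic,
    credible_interval,
    fit_independent,
    fit_pooled,
    fit_variable_wf,
    grid_posterior_oracle,
    posterior_mode,
    split_rhat,
)

FAST = McmcSettings(chains=8, tune=300, draws=2000, thin=2)


class TestGridOracle:
    def test_normalized(self, comparison_factory):
        g = grid_posterior_oracle(comparison_factory(true_jnd=20.0, seed=1))
        assert g.integral() == pytest.approx(1.0, abs=1e-6)

    def test_zero_comparisons_returns_prior(self):
        prior = PriorSpec()
        g = grid_posterior_oracle(pd.DataFrame(columns=["x_percent", "response"]), prior)
        lo, hi = prior.support
        assert np.allclose(g.density, 1.0 / (hi - lo))

    def test_mean_near_truth_at_large_n(self, comparison_factory):
        comps = comparison_factory(true_jnd=20.0, n=2000, seed=2, x_span=(-60, 60))
        assert grid_posterior_oracle(comps).mean() == pytest.approx(20.0, abs=2.0)


class TestPosteriorMode:
    def test_degenerate_draws(self):
        mode = posterior_mode(np.full(200, 20.0), (0.1, 70.0))
        assert mode.value == 20.0 and not mode.flat

    def test_known_truncated_normal(self, rng):
        a, b = (0 - 25) / 2, (70 - 25) / 2
        draws = truncnorm.rvs(a, b, loc=25, scale=2, size=16_000, random_state=rng)
        mode = posterior_mode(draws, (0.1, 70.0))
        assert mode.value == pytest.approx(25.0, abs=0.5)
        assert not mode.flat

    def test_uniform_draws_flagged_flat(self, rng):
        mode = posterior_mode(rng.uniform(0.1, 70.0, 16_000), (0.1, 70.0))
        assert mode.flat

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_mode(np.ones(50), (0.1, 70.0))


class TestCredibleInterval:
    def test_uniform_quantiles(self):
        draws = np.arange(1, 10_001) / 100.0
        lo, hi = credible_interval(draws)
        assert lo == pytest.approx(2.5, abs=0.05)
        assert hi == pytest.approx(97.5, abs=0.05)

    def test_constant_draws_zero_width(self):
        lo, hi = credible_interval(np.full(200, 20.0))
        assert lo == hi == 20.0

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            credible_interval(np.arange(200.0), level=1.5)


class TestWaic:
    def test_constant_matrix(self):
        c = -0.6
        w = compute_waic(np.full((150, 12), c))
        assert w.score == pytest.approx(12 * c, abs=1e-12)
        assert w.p_eff == pytest.approx(0.0, abs=1e-12)

    def test_matches_literal_two_pass_oracle(self, rng):
        ll = rng.normal(-0.7, 0.3, size=(200, 50))
        w = compute_waic(ll)
        score = 0.0
        p_eff = 0.0
        for i in range(50):
            col = ll[:, i]
            lppd = logsumexp(col) - np.log(len(col))
            p = np.var(col, ddof=1)
            score += lppd - p
            p_eff += p
        assert w.score == pytest.approx(score, abs=1e-8)
        assert w.p_eff == pytest.approx(p_eff, abs=1e-8)

    def test_duplicate_response_duplicates_contribution(self, rng):
        ll = rng.normal(-0.7, 0.3, size=(150, 10))
        dup = np.hstack([ll, ll[:, [0]]])
        w0, w1 = compute_waic(ll), compute_waic(dup)
        assert w1.score == pytest.approx(w0.score + w0.pointwise[0], abs=1e-10)

    def test_matches_arviz(self, rng):
        """Independent cross-check of the WAIC formula against arviz."""
        az = pytest.importorskip("arviz")
        ll = rng.normal(-0.7, 0.3, size=(400, 30))
        s = ll.shape[0]
        mine = compute_waic(ll)
        idata = az.from_dict(log_likelihood={"y": ll[None]})
        theirs = az.waic(idata, scale="log")
        # arviz penalizes with the population variance (ddof=0); this package
        # uses the sample variance (ddof=1) — rescale before comparing
        p_pop = mine.p_eff * (s - 1) / s
        assert p_pop == pytest.approx(float(theirs.p_waic), abs=1e-6)
        lppd = mine.score + mine.p_eff
        assert lppd - p_pop == pytest.approx(float(theirs.elpd_waic), abs=1e-6)

    def test_non_finite_rejected(self):
        ll = np.zeros((150, 3))
        ll[0, 0] = np.inf
        with pytest.raises(ValueError):
            compute_waic(ll)

    def test_cohort_waic_matches_full_matrix(self, comparison_factory, rng):
        """Blockwise cohort WAIC equals compute_waic on the assembled matrix."""
        comps = comparison_factory(true_jnd=20.0, n=40, seed=4)
        x = comps["x_percent"].to_numpy()
        r = comps["response"].to_numpy(float)
        draws = rng.uniform(5, 60, 300)
        from metabosense.psychometrics import pointwise_log_likelihood

        full = compute_waic(pointwise_log_likelihood(x, r, draws))
        idx = np.arange(40)
        halves = cohort_waic(
            40,
            [(draws, x[:20], r[:20], idx[:20]), (draws, x[20:], r[20:], idx[20:])],
        )
        assert halves.score == pytest.approx(full.score, abs=1e-10)
        np.testing.assert_allclose(halves.pointwise, full.pointwise, atol=1e-12)


class TestCompareModels:
    def test_identical_models_tie(self, rng):
        ll = rng.normal(-0.7, 0.2, size=(150, 20))
        w = compute_waic(ll)
        table = compare_models({"a": w, "b": w})
        assert np.allclose(table["d_score"], 0.0)
        assert np.allclose(table["d_se"], 0.0)

    def test_mismatched_response_sets_rejected(self, rng):
        w1 = compute_waic(rng.normal(size=(150, 20)))
        w2 = compute_waic(rng.normal(size=(150, 21)))
        with pytest.raises(ValueError):
            compare_models({"a": w1, "b": w2})


class TestSplitRhat:
    def test_identical_chains_unity(self):
        chain = np.sin(np.linspace(0, 10, 400))
        assert split_rhat(np.tile(chain, (4, 1))) == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_large(self):
        chains = np.vstack([np.random.default_rng(0).normal(0, 1, 400),
                            np.random.default_rng(1).normal(10, 1, 400)])
        assert split_rhat(chains) > 2.0


class TestFits:
    def test_empty_comparisons_rejected(self):
        with pytest.raises(ValueError):
            fit_independent(pd.DataFrame(columns=["x_percent", "response"]))

    def test_large_n_recovery(self, comparison_factory):
        comps = comparison_factory(true_jnd=20.0, n=2000, seed=5, x_span=(-60, 60))
        fit = fit_independent(comps, mcmc=FAST, seed=1)
        assert fit.point_estimate == pytest.approx(20.0, abs=2.0)

    def test_mcmc_agrees_with_grid_oracle(self, comparison_factory):
        comps = comparison_factory(true_jnd=25.0, n=99, seed=6)
        fit = fit_independent(comps, mcmc=McmcSettings(16, 500, 16_000, 4), seed=2)
        g = grid_posterior_oracle(comps)
        assert abs(fit.draws.mean() - g.mean()) < 0.5

    def test_uninformative_responses_push_mass_up(self, rng):
        """Fair-coin responses exclude only low JNDs: upper CI near prior bound."""
        x = rng.uniform(-40, 60, 99)
        r = rng.integers(0, 2, 99)
        fit = fit_independent(pd.DataFrame({"x_percent": x, "response": r}), mcmc=FAST, seed=3)
        assert fit.ci95[1] > 50.0
        g = grid_posterior_oracle(pd.DataFrame({"x_percent": x, "response": r}))
        assert abs(fit.draws.mean() - g.mean()) < 1.5

    def test_deterministic_given_seed(self, comparison_factory):
        comps = comparison_factory(true_jnd=20.0, seed=7)
        f1 = fit_independent(comps, mcmc=FAST, seed=9)
        f2 = fit_independent(comps, mcmc=FAST, seed=9)
        np.testing.assert_array_equal(f1.draws, f2.draws)
        assert f1.point_estimate == f2.point_estimate

    def test_pooled_single_participant_matches_independent(self, comparison_factory):
        comps = comparison_factory(true_jnd=20.0, seed=8)
        heavy = McmcSettings(16, 500, 8000, 4)
        ind = fit_independent(comps, mcmc=heavy, seed=4)
        pooled = fit_pooled(comps, mcmc=heavy, seed=5)
        assert abs(ind.draws.mean() - pooled.draws.mean()) < 1.0

    def test_pooled_homogeneous_cohort_recovery(self, comparison_factory):
        cohort = pd.concat(
            [comparison_factory(20.0, n=99, seed=10 + i, participant_id=f"P{i:02d}") for i in range(10)],
            ignore_index=True,
        )
        pooled = fit_pooled(cohort, mcmc=FAST, seed=6)
        assert pooled.point_estimate == pytest.approx(20.0, abs=2.0)

    def test_pooled_heterogeneous_brackets_truth(self, comparison_factory):
        cohort = pd.concat(
            [
                comparison_factory(8.0, n=99, seed=30, participant_id="PA"),
                comparison_factory(60.0, n=99, seed=31, participant_id="PB"),
            ],
            ignore_index=True,
        )
        pooled = fit_pooled(cohort, mcmc=FAST, seed=7)
        assert 8.0 < pooled.point_estimate < 60.0


class TestVariableWf:
    def test_median_split_bookkeeping(self, rng):
        comps = pd.DataFrame(
            {
                "A_w_per_kg": [2.0, 3.0, 4.0, 5.0],
                "x_percent": [5.0, -5.0, 10.0, -10.0],
                "response": [1, 0, 1, 0],
            }
        )
        # too few comparisons per half to sample meaningfully, so check the
        # split logic through the public fit with a padded frame
        pad = pd.concat([comps] * 30, ignore_index=True)
        fit = fit_variable_wf(pad, mcmc=FAST, seed=8)
        assert fit.split_value == pytest.approx(3.5)
        assert fit.is_high.sum() == len(pad) // 2

    def test_identical_references_rejected(self):
        comps = pd.DataFrame(
            {"A_w_per_kg": [3.0] * 10, "x_percent": np.linspace(-10, 10, 10), "response": [0, 1] * 5}
        )
        with pytest.raises(ValueError):
            fit_variable_wf(comps)

    def test_recovers_distinct_jnds_by_reference_magnitude(self, rng):
        """JND 10% below the median reference and 40% above -> ordered modes."""
        from metabosense.synthetic import simulate_response

        ordered = 0
        reps = 16
        for rep in range(reps):
            gen = np.random.default_rng(100 + rep)
            a = gen.uniform(1.5, 6.6, 99)
            x = gen.uniform(-40, 60, 99)
            med = np.median(a)
            jnds = np.where(a < med, 10.0, 40.0)
            r = [simulate_response(xi, ji, 0.02, gen) for xi, ji in zip(x, jnds)]
            comps = pd.DataFrame({"A_w_per_kg": a, "x_percent": x, "response": r})
            fit = fit_variable_wf(comps, mcmc=FAST, seed=rep)
            ordered += fit.low.point_estimate < fit.high.point_estimate
        assert ordered >= 13

    def test_constant_jnd_gives_overlapping_intervals(self, comparison_factory):
        overlaps = 0
        reps = 12
        for rep in range(reps):
            comps = comparison_factory(true_jnd=20.0, n=99, seed=200 + rep)
            fit = fit_variable_wf(comps, mcmc=FAST, seed=rep)
            lo1, hi1 = fit.low.ci95
            lo2, hi2 = fit.high.ci95
            overlaps += max(lo1, lo2) < min(hi1, hi2)
        assert overlaps >= 10
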