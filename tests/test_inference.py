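"""Hierarchical model construction, likelihood correctness and sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from avgain import (
    CohortSpec,
    HierarchicalObserverModel,
    ModelSpec,
    ObserverParams,
    log_likelihood,
    probability_of_direction,
    simulate_cohort,
)
from avgain.hierarchical import SpecificationError, run_ensemble
from avgain.observer import psychometric_s0
from avgain.predictive import prior_predictive
from tests.conftest import study_population


class TestLogLikelihood:
    def _trials(self, n=10, seed=0):
        spec = CohortSpec(n_rats=1, trials_per_rat=n,
                          condition_weights=(0.5, 0.5, 0, 0), seed=seed)
        return simulate_cohort(spec)

    def test_pure_guessing_gives_log_half(self):
        trials = self._trials(20)
        params = ObserverParams(sigma=1.0, gamma=(1.0,) * 5,
                                eps_h=0.5, eps_l=0.5)
        ll = log_likelihood(params, trials)
        assert np.allclose(ll, math.log(0.5), atol=1e-12)

    def test_single_trial_matches_psychometric(self):
        trials = self._trials(1, seed=1)
        params = ObserverParams(sigma=0.6, gamma=(1.2, 1.1, 1.0, 0.9, 0.8),
                                eps_h=0.05, eps_l=0.1)
        row = trials.iloc[0]
        p = psychometric_s0(row["visual_tf_hz"],
                            int(row["intensity_level"]) - 1, params, 2.12)
        expected = math.log(p if row["choice"] == "H" else 1 - p)
        assert log_likelihood(params, trials)[0] == pytest.approx(expected, abs=1e-12)

    def test_total_matches_brute_force_product(self):
        trials = self._trials(10, seed=2)
        params = ObserverParams(sigma=0.7, gamma=(1.3, 1.2, 1.1, 1.0, 0.9),
                                eps_h=0.02, eps_l=0.08)
        product = 1.0
        for _, row in trials.iterrows():
            p = psychometric_s0(row["visual_tf_hz"],
                                int(row["intensity_level"]) - 1, params, 2.12)
            product *= p if row["choice"] == "H" else 1 - p
        assert log_likelihood(params, trials).sum() == pytest.approx(
            math.log(product), abs=1e-9
        )

    def test_auditory_only_trial_rejected(self):
        trials = self._trials(5)
        trials.loc[0, "visual_tf_hz"] = np.nan
        with pytest.raises(ValueError, match="without a visual stimulus"):
            log_likelihood(ObserverParams(sigma=1.0, gamma=(1.0,)), trials)


class TestModelLikelihoodConsistency:
    def test_model_pointwise_matches_standalone(self, small_cohort):
        trials, true_params, _ = small_cohort
        model = HierarchicalObserverModel(trials, ModelSpec(1, 5))
        theta = model.theta_from_params(true_params)
        model_ll = model.pointwise_loglik(theta[None, :])[0]
        total = 0.0
        for rat in model.rats:
            sub = model.trials[model.trials["rat_id"] == rat]
            total += log_likelihood(true_params[rat], sub).sum()
        assert model_ll.sum() == pytest.approx(total, abs=1e-9)

    def test_single_gain_nested_in_five_gain(self, small_cohort):
        trials, true_params, _ = small_cohort
        flat = {
            r: ObserverParams(sigma=p.sigma, gamma=(p.gamma[0],) * 5,
                              eps_h=p.eps_h, eps_l=p.eps_l)
            for r, p in true_params.items()
        }
        m5 = HierarchicalObserverModel(trials, ModelSpec(1, 5))
        m1 = HierarchicalObserverModel(trials, ModelSpec(1, 1))
        ll5 = m5.pointwise_loglik(m5.theta_from_params(flat)[None, :])[0]
        flat1 = {r: ObserverParams(sigma=p.sigma, gamma=(p.gamma[0],),
                                   eps_h=p.eps_h, eps_l=p.eps_l)
                 for r, p in flat.items()}
        ll1 = m1.pointwise_loglik(m1.theta_from_params(flat1)[None, :])[0]
        assert np.allclose(ll5, ll1, atol=1e-9)

    def test_missing_levels_raise_specification_error(self, small_cohort):
        trials, _, _ = small_cohort
        broken = trials.copy()
        broken["intensity_level"] = np.nan
        with pytest.raises((SpecificationError, ValueError)):
            HierarchicalObserverModel(broken, ModelSpec(1, 5))


class TestSampling:
    def test_conjugate_gaussian_toy_matches_analytic_posterior(self):
        # observe x_t ~ N(gamma * s_t, rho^2) with flat prior on gamma:
        # the posterior is exactly Normal; the ensemble driver must match it
        rng = np.random.default_rng(0)
        s = rng.uniform(0.5, 4.0, size=40)
        rho, gamma_true = 0.8, 1.2
        x = rng.normal(gamma_true * s, rho)
        post_var = rho**2 / np.sum(s**2)
        post_mean = np.sum(x * s) / np.sum(s**2)

        def logp(th):
            g = th[:, 0]
            return -0.5 * ((x[None, :] - g[:, None] * s[None, :]) ** 2).sum(1) / rho**2

        draws = run_ensemble(logp, np.array([[1.0]]), n_walkers=32,
                             tune=400, draws=4000, seed=1)
        mcse = math.sqrt(post_var / 500)  # conservative effective size
        assert draws.mean() == pytest.approx(post_mean, abs=4 * mcse)
        assert draws.std() == pytest.approx(math.sqrt(post_var), rel=0.15)

    def test_same_seed_gives_identical_draws(self):
        trials = simulate_cohort(
            CohortSpec(n_rats=2, trials_per_rat=300,
                       population=study_population(), seed=5)
        )
        model = HierarchicalObserverModel(trials, ModelSpec(1, 5))
        a = model.fit(chains=2, tune=300, draws=200, seed=7)
        b = model.fit(chains=2, tune=300, draws=200, seed=7)
        assert np.array_equal(
            a.idata.posterior["mu_gamma"].values,
            b.idata.posterior["mu_gamma"].values,
        )

    def test_loglik_array_shape(self, fitted_small):
        model, results, _, _ = fitted_small
        ll = results.idata.log_likelihood["choice"]
        assert ll.shape == (2, 500, model.n_trials)

    def test_summary_reports_standard_diagnostics(self, fitted_small):
        _, results, _, _ = fitted_small
        s = results.summary()
        for col in ("mean", "sd", "hdi_3%", "hdi_97%", "mcse_mean", "mcse_sd",
                    "ess_bulk", "ess_tail", "r_hat"):
            assert col in s.columns
        assert s["ess_bulk"].min() > 400
        assert s["r_hat"].max() <= 1.05

    def test_shrinkage_toward_population_mean(self, fitted_small):
        # partial pooling: posterior per-rat gains sit between the rat's own
        # empirical estimate and the population mean in most cells
        model, results, true_params, _ = fitted_small
        post = results.idata.posterior
        mu_hat = post["mu_gamma"].mean(("chain", "draw")).values
        g_post = post["gamma"].mean(("chain", "draw")).values  # (R, G)
        contracted = 0
        total = 0
        for ri, rat in enumerate(model.rats):
            sub = model.trials[model.trials["rat_id"] == rat]
            for lv in range(5):
                cell = sub[sub["intensity_level"] == lv + 1]
                prop = cell.groupby("visual_tf_hz")["choice"].apply(
                    lambda c: (c == "H").mean()
                )
                if len(prop) < 5:
                    continue
                z = ndtri(np.clip(prop.to_numpy(), 0.02, 0.98))
                slope, inter = np.polyfit(prop.index.to_numpy(), z, 1)
                if slope <= 0 or inter >= 0:
                    continue
                sigma_emp = -2.12 / inter
                g_emp = slope * sigma_emp
                total += 1
                if abs(g_post[ri, lv] - mu_hat[lv]) <= abs(g_emp - mu_hat[lv]) + 0.02:
                    contracted += 1
        assert total >= 10
        assert contracted / total >= 0.7


class TestPriorPredictive:
    def test_envelopes_identical_across_gain_groups(self):
        pp = prior_predictive(n_sims=800, seed=0)
        piv = pp.pivot(index="visual_tf_hz", columns="gamma_group", values="mean")
        spread = (piv.max(axis=1) - piv.min(axis=1)).max()
        # symmetric priors: group differences are pure sampling noise
        assert spread < 4 * pp["sd"].mean() / math.sqrt(800)

    def test_needs_no_data(self):
        pp = prior_predictive(n_sims=50, seed=1)
        assert len(pp) == 5 * 9
        assert pp["sd"].gt(0).all()


class TestProbabilityOfDirection:
    def test_all_positive_draws(self):
        pd_val, p = probability_of_direction(np.abs(np.random.default_rng(0)
                                                    .normal(1, 0.1, 500)))
        assert pd_val == 1.0
        assert p == 0.0

    def test_symmetric_draws_near_half(self):
        x = np.random.default_rng(1).normal(0.0, 1.0, 200_000)
        pd_val, _ = probability_of_direction(x)
        assert 0.5 <= pd_val < 0.51

    def test_normal_tail_oracle(self):
        # Normal(-0.17, 0.19) draws: pd -> Phi(0.17 / 0.19)
        rng = np.random.default_rng(2)
        x = rng.normal(-0.17, 0.19, 400_000)
        pd_val, p = probability_of_direction(x)
        expected = 0.5 * (1 + math.erf((0.17 / 0.19) / math.sqrt(2)))
        assert pd_val == pytest.approx(expected, abs=0.005)
        assert p == pytest.approx(2 * (1 - expected), abs=0.01)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            probability_of_direction(np.ones(10))
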