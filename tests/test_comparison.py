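"""PSIS-LOO ELPD, the exact refit oracle and model ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from avgain import (
    CohortSpec,
    HierarchicalObserverModel,
    ModelSpec,
    PopulationParams,
    simulate_cohort,
)
from avgain.comparison import (
    ComparisonError,
    _prior_predictive_logdens,
    compare_models,
    exact_loo_oracle,
    fit_linear_gamma_summary,
    pointwise_elpd,
)
from avgain.cohort import LEVEL_INTENSITIES_DB
from tests.conftest import study_population


@pytest.fixture(scope="module")
def tiny_fit():
    """A quick 2-rat fit reused across ELPD formula tests."""
    trials = simulate_cohort(
        CohortSpec(n_rats=2, trials_per_rat=150,
                   population=study_population(), seed=21)
    )
    model = HierarchicalObserverModel(trials, ModelSpec(1, 5))
    return model, model.fit(chains=2, tune=400, draws=400, seed=3)


class TestPointwiseElpd:
    def test_degenerate_posterior_gives_exact_sum(self, tiny_fit):
        # identical likelihood across draws: weights are uniform and the
        # LOO density collapses to the pointwise likelihood itself
        import arviz as az
        import xarray as xr

        from avgain.hierarchical import HierarchicalObserverResults

        model, results = tiny_fit
        const = xr.Dataset(
            {
                "choice": xr.DataArray(
                    np.full((2, 400, model.n_trials), math.log(0.3)),
                    dims=("chain", "draw", "trial"),
                )
            }
        )
        degen = HierarchicalObserverResults(
            model,
            az.InferenceData(posterior=results.idata.posterior,
                             log_likelihood=const),
            results.acceptance_fraction,
        )
        out = pointwise_elpd(degen)
        assert out.elpd == pytest.approx(model.n_trials * math.log(0.3), abs=1e-6)
        assert out.se == pytest.approx(0.0, abs=1e-9)

    def test_order_invariance_of_the_sum(self, tiny_fit):
        model, results = tiny_fit
        out = pointwise_elpd(results)
        rng = np.random.default_rng(0)
        perm = rng.permutation(out.n_trials)
        assert out.pointwise[perm].sum() == pytest.approx(out.elpd, abs=1e-9)

    def test_pareto_k_per_trial(self, tiny_fit):
        model, results = tiny_fit
        out = pointwise_elpd(results)
        assert len(out.pareto_k) == out.n_trials
        assert out.se > 0

    def test_duplicating_trials_doubles_magnitude(self):
        pop = study_population()
        trials = simulate_cohort(
            CohortSpec(n_rats=2, trials_per_rat=120, population=pop, seed=22)
        )
        doubled = pd.concat([trials, trials], ignore_index=True)
        e1 = pointwise_elpd(
            HierarchicalObserverModel(trials, ModelSpec(1, 1)).fit(
                chains=2, tune=400, draws=400, seed=4
            )
        )
        e2 = pointwise_elpd(
            HierarchicalObserverModel(doubled, ModelSpec(1, 1)).fit(
                chains=2, tune=400, draws=400, seed=4
            )
        )
        assert e2.elpd == pytest.approx(2 * e1.elpd, rel=0.15)

    def test_requires_stored_loglik(self, tiny_fit):
        model, _ = tiny_fit
        res = model.fit(chains=2, tune=200, draws=100, seed=5, store_loglik=False)
        with pytest.raises(RuntimeError, match="log-likelihood"):
            pointwise_elpd(res)


class TestExactLooOracle:
    def test_single_trial_equals_prior_predictive(self):
        trials = simulate_cohort(
            CohortSpec(n_rats=1, trials_per_rat=1,
                       condition_weights=(1, 0, 0, 0),
                       population=study_population(), seed=30)
        )
        spec = ModelSpec(1, 1)
        out = exact_loo_oracle(spec, trials, budget=5, seed=9)
        direct = _prior_predictive_logdens(trials.iloc[0], spec, None, seed=9)
        assert out.elpd == pytest.approx(direct, abs=1e-12)

    def test_budget_refusal(self):
        trials = simulate_cohort(CohortSpec(n_rats=2, trials_per_rat=50, seed=0))
        with pytest.raises(ValueError, match="budget"):
            exact_loo_oracle(ModelSpec(1, 1), trials, budget=10)

    def test_agrees_with_psis_on_tiny_set(self):
        pop = study_population(mu_gamma=(1.2,), sd_gamma=(0.1,))
        trials = simulate_cohort(
            CohortSpec(n_rats=3, trials_per_rat=10,
                       condition_weights=(1, 0, 0, 0), population=pop, seed=31)
        )
        spec = ModelSpec(1, 1)
        model = HierarchicalObserverModel(trials, spec)
        psis = pointwise_elpd(model.fit(chains=2, tune=400, draws=500, seed=10,
                                        thin=10, n_mh_chains=64))
        exact = exact_loo_oracle(spec, trials, budget=40, seed=10,
                                 chains=2, tune=300, draws=300)
        assert abs(psis.elpd - exact.elpd) <= 2 * max(psis.se, exact.se)


class TestCompareModels:
    def test_single_model_has_zero_delta(self, tiny_fit):
        _, results = tiny_fit
        out = pointwise_elpd(results, name="only")
        table = compare_models({"only": out})
        assert table.loc["only", "delta_elpd"] == 0.0

    def test_mismatched_datasets_rejected(self, tiny_fit):
        model, results = tiny_fit
        a = pointwise_elpd(results, name="a")
        other = simulate_cohort(
            CohortSpec(n_rats=2, trials_per_rat=150,
                       population=study_population(), seed=99)
        )
        b = pointwise_elpd(
            HierarchicalObserverModel(other, ModelSpec(1, 5)).fit(
                chains=2, tune=200, draws=100, seed=1
            ),
            name="b",
        )
        with pytest.raises(ComparisonError):
            compare_models({"a": a, "b": b})

    def test_deltas_nonpositive_and_sorted(self, tiny_fit):
        model, results = tiny_fit
        e5 = pointwise_elpd(results, name="1s5g")
        m1 = HierarchicalObserverModel(model.trials, ModelSpec(1, 1))
        e1 = pointwise_elpd(m1.fit(chains=2, tune=400, draws=400, seed=6),
                            name="1s1g")
        table = compare_models({"1s5g": e5, "1s1g": e1})
        assert table["delta_elpd"].iloc[0] == 0.0
        assert (table["delta_elpd"] <= 0).all()
        assert table["elpd"].is_monotonic_decreasing


class TestLinearGainModel:
    SLOPE, INTERCEPT = -0.01, 1.6

    @pytest.fixture(scope="class")
    def linear_fit(self):
        mu = tuple(self.INTERCEPT + self.SLOPE * i for i in LEVEL_INTENSITIES_DB)
        pop = study_population(mu_gamma=mu)
        trials = simulate_cohort(
            CohortSpec(n_rats=6, trials_per_rat=800, population=pop, seed=41)
        )
        spec = ModelSpec(1, 5, gamma_structure="linear_in_intensity",
                         intensity_values=LEVEL_INTENSITIES_DB)
        return HierarchicalObserverModel(trials, spec).fit(
            chains=2, tune=800, draws=500, seed=12
        )

    def test_slope_and_intercept_recovered(self, linear_fit):
        out = fit_linear_gamma_summary(linear_fit)
        assert abs(out["slope_mean"] - self.SLOPE) < 2.5 * out["slope_sd"]
        assert abs(out["intercept_mean"] - self.INTERCEPT) < 2.5 * out["intercept_sd"]

    def test_implied_level_gains_follow_the_line(self, linear_fit):
        out = fit_linear_gamma_summary(linear_fit)
        implied = np.asarray(out["implied_mu_gamma_mean"])
        truth = self.INTERCEPT + self.SLOPE * np.asarray(LEVEL_INTENSITIES_DB)
        assert np.all(np.abs(implied - truth)
                      < 3 * np.asarray(out["implied_mu_gamma_sd"]) + 0.05)

    def test_zero_slope_generator_shows_no_direction(self):
        pop = study_population(mu_gamma=(1.15,) * 5)
        trials = simulate_cohort(
            CohortSpec(n_rats=6, trials_per_rat=600, population=pop, seed=42)
        )
        spec = ModelSpec(1, 5, gamma_structure="linear_in_intensity",
                         intensity_values=LEVEL_INTENSITIES_DB)
        res = HierarchicalObserverModel(trials, spec).fit(
            chains=2, tune=800, draws=500, seed=13
        )
        pd_val, _ = res.probability_of_direction("gamma_slope")
        assert pd_val < 0.95

    def test_wrong_model_rejected(self, tiny_fit):
        _, results = tiny_fit
        with pytest.raises(RuntimeError, match="linear"):
            fit_linear_gamma_summary(results)
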