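"""Shared fixtures: study populations, synthetic cohorts and cached fits.

Heavy posterior fits are session-scoped so that the inference, comparison
and predictive-check tests share one sampled posterior instead of refitting.
"""

from __future__ import annotations

import numpy as np
import pytest

from avgain import (
    CalibrationConstants,
    CohortSpec,
    HierarchicalObserverModel,
    ModelSpec,
    PopulationParams,
    StimulusSet,
    simulate_cohort,
)

#: Gain means for the recovery/selection studies: monotone in sound level
#: with 0.15 spacing, wide enough for a desk-scale cohort to order.
STUDY_MU_GAMMA = (1.50, 1.35, 1.20, 1.05, 0.90)

#: Lapse-simplex concentration emulating task-proficient animals
#: (training required sustained >=70% accuracy, bounding total lapse).
PROFICIENT_LAPSES = (1.0, 1.0, 8.0)


def study_population(**overrides) -> PopulationParams:
    base = dict(
        mu_gamma=STUDY_MU_GAMMA,
        sd_gamma=(0.1,) * 5,
        k_sigma=10.0,
        theta_sigma=0.06,
        lapse_conc=PROFICIENT_LAPSES,
    )
    base.update(overrides)
    return PopulationParams(**base)


@pytest.fixture(scope="session")
def stimset() -> StimulusSet:
    return StimulusSet()


@pytest.fixture(scope="session")
def calib() -> CalibrationConstants:
    return CalibrationConstants()


@pytest.fixture(scope="session")
def small_cohort():
    """6 rats x 800 trials from the graded-gain study population."""
    spec = CohortSpec(
        n_rats=6, trials_per_rat=800, population=study_population(), seed=3
    )
    trials, true_params = simulate_cohort(spec, return_params=True)
    return trials, true_params, spec


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """A fitted (1 sigma, 5 gamma) model on the small cohort."""
    trials, true_params, spec = small_cohort
    model = HierarchicalObserverModel(trials, ModelSpec(n_sigma=1, n_gamma=5))
    results = model.fit(chains=2, tune=800, draws=500, seed=11)
    return model, results, true_params, spec
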