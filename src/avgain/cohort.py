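"""Synthetic rat cohorts for the audiovisual temporal-frequency task.

Generates trial tables that emulate the test phase of the behavioural
experiment: each trial falls into one of four categories (visual grating
plus fixed-amplitude sound, grating plus one of the 81 audiovisual AM
pairings, grating alone, or AM sound alone), visual stimuli are drawn
uniformly subject to the task's rule that at most three consecutive trials
may show the same visual class, choices come from the lapse-extended
psychometric model with per-rat parameters drawn from the population
distributions, and response times from a configurable truncated-lognormal
model.  Everything is reproducible from a single seed.

The population defaults follow the fitted linear relation between gain and
average sound level (slope -8.6e-3 per dB, intercept 1.636) evaluated at
the five intensity-level means, so the default cohort exhibits the
sound-intensity-dependent compression the model is built to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .acoustics import (
    AM_FREQUENCIES,
    N_INTENSITY_LEVELS,
    SoundCondition,
    intensity_level_of,
)
from .observer import ObserverParams, StimulusSet, psychometric_s0

__all__ = [
    "PopulationParams",
    "CohortSpec",
    "ScheduleConstraintError",
    "TrialSchemaError",
    "REQUIRED_COLUMNS",
    "sample_rat_params",
    "build_schedule",
    "simulate_cohort",
    "write_trials",
    "read_trials",
]

#: Mean measured intensity (dB) of each of the five levels: silence, AM 0.25 Hz,
#: AM 0.82 Hz, AM 1.32-4 Hz, fixed-amplitude.
LEVEL_INTENSITIES_DB: tuple[float, ...] = (32.0, 48.5, 64.2, 70.7, 74.8)

_LINEAR_SLOPE = -8.6e-3   # gain change per dB of average sound level
_LINEAR_INTERCEPT = 1.636

REQUIRED_COLUMNS = (
    "rat_id",
    "session",
    "visual_tf_hz",
    "sound_kind",
    "sound_tf_hz",
    "intensity_level",
    "choice",
    "response_time_s",
)

MIN_RT = 0.3   # responses within 300 ms were aborted
MAX_RT = 2.0   # response window


class ScheduleConstraintError(RuntimeError):
    """Raised when the trial-category weights make the schedule infeasible."""


class TrialSchemaError(ValueError):
    """Raised when a trial table violates the required schema."""


@dataclass(frozen=True)
class PopulationParams:
    """Group-level hyperparameters of the hierarchical observer.

    Per-rat parameters are drawn as gamma_n ~ Normal(mu_gamma[n],
    sd_gamma[n]^2) (truncated to positive values in the generator only),
    sigma ~ Gamma(shape k_sigma, scale theta_sigma), and the lapse simplex
    (eps_L, eps_H, engagement) ~ Dirichlet(lapse_conc).  Optional fields
    support the encoding-offset (lambda) and linear-gain model variants.
    """

    mu_gamma: tuple[float, ...] = tuple(
        _LINEAR_INTERCEPT + _LINEAR_SLOPE * i for i in LEVEL_INTENSITIES_DB
    )
    sd_gamma: tuple[float, ...] = (0.1,) * N_INTENSITY_LEVELS
    k_sigma: float = 10.0
    theta_sigma: float = 0.06
    lapse_conc: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mu_lambda: float | None = None
    sd_lambda: float | None = None
    slope: float | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        if len(self.mu_gamma) != len(self.sd_gamma):
            raise ValueError("mu_gamma and sd_gamma must have equal length")
        if any(s <= 0 for s in self.sd_gamma):
            raise ValueError("sd_gamma entries must be positive")
        if self.k_sigma <= 0 or self.theta_sigma <= 0:
            raise ValueError("Gamma hyperparameters must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``condition_weights`` orders the four trial categories (V+fixed, V+AM,
    V-only, A-only); the default is proportional to the cell counts of the
    test-phase design matrix (9 fixed-sound cells, 81 AM pairings, 9
    visual-only, 9 auditory-only).
    """

    n_rats: int = 10
    trials_per_rat: int = 1000
    condition_weights: tuple[float, float, float, float] = (
        9 / 108, 81 / 108, 9 / 108, 9 / 108
    )
    population: PopulationParams = field(default_factory=PopulationParams)
    rt_median: float = 0.7        # lognormal RT median (s)
    rt_gsd: float = 1.4           # geometric standard deviation
    trials_per_session: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rats < 1 or self.trials_per_rat < 1:
            raise ValueError("cohort must contain at least one rat and one trial")
        w = np.asarray(self.condition_weights, dtype=float)
        if w.min() < 0 or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("condition_weights must be non-negative and sum to 1")


CATEGORIES = ("v_fixed", "v_am", "v_only", "a_only")


def sample_rat_params(
    population: PopulationParams, rng: np.random.Generator
) -> ObserverParams:
    """Draw one rat's observer parameters from the population distributions.

    Gains are redrawn until positive (the inference model keeps the
    untruncated Normal prior; the generator must produce valid observers).
    """
    eps_l, eps_h, _ = rng.dirichlet(population.lapse_conc)
    sigma = rng.gamma(shape=population.k_sigma, scale=population.theta_sigma)
    gamma = []
    for mu, sd in zip(population.mu_gamma, population.sd_gamma):
        g = rng.normal(mu, sd)
        while g <= 0:
            g = rng.normal(mu, sd)
        gamma.append(g)
    lam = 0.0
    if population.mu_lambda is not None:
        lam = rng.normal(population.mu_lambda, population.sd_lambda or 0.0)
    return ObserverParams(
        sigma=float(sigma), gamma=tuple(gamma),
        eps_h=float(eps_h), eps_l=float(eps_l), lam=float(lam),
    )


def _visual_class(tf: float, s0: float, rng: np.random.Generator) -> str:
    if math.isclose(tf, s0):
        return "H" if rng.random() < 0.5 else "L"
    return "H" if tf > s0 else "L"


def build_schedule(
    spec: CohortSpec,
    stimset: StimulusSet | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one rat's ordered trial schedule.

    Trial categories follow ``condition_weights``; within a category every
    stimulus (visual TF, and AM frequency where applicable) is equally
    likely.  No more than three consecutive trials may show the same visual
    class; when a draw would violate the rule the visual TF is redrawn from
    the opposite class.  Auditory-only trials show no grating and reset the
    run counter.
    """
    stimset = stimset or StimulusSet()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    tfs = np.asarray(stimset.all_tfs)
    low = [t for t in tfs if t < stimset.s0]
    high = [t for t in tfs if t > stimset.s0]
    if not low or not high:
        raise ScheduleConstraintError("both visual classes must be non-empty")

    cats = rng.choice(len(CATEGORIES), size=spec.trials_per_rat,
                      p=np.asarray(spec.condition_weights))
    rows = []
    run_class, run_len = None, 0
    for i in range(spec.trials_per_rat):
        cat = CATEGORIES[cats[i]]
        if cat == "a_only":
            am_tf = float(rng.choice(AM_FREQUENCIES))
            rows.append((cat, np.nan, "am", am_tf))
            run_class, run_len = None, 0
            continue
        tf = float(rng.choice(tfs))
        cls = _visual_class(tf, stimset.s0, rng)
        if cls == run_class and run_len >= 3:
            # redraw from the opposite class; the boundary stimulus enters
            # with half weight (it belongs to either class equally often),
            # which keeps the per-stimulus marginals exactly uniform
            other = low if run_class == "H" else high
            pool = np.array([*other, stimset.s0])
            w = np.array([1.0] * len(other) + [0.5])
            tf = float(rng.choice(pool, p=w / w.sum()))
            cls = "H" if run_class == "L" else "L"
        if cat == "v_fixed":
            rows.append((cat, tf, "fixed", np.nan))
        elif cat == "v_only":
            rows.append((cat, tf, "silence", np.nan))
        else:
            am_tf = float(rng.choice(AM_FREQUENCIES))
            rows.append((cat, tf, "am", am_tf))
        if cls == run_class:
            run_len += 1
        else:
            run_class, run_len = cls, 1
    return pd.DataFrame(rows, columns=["category", "visual_tf_hz", "sound_kind",
                                       "sound_tf_hz"])


def _sound_condition(kind: str, sound_tf: float) -> SoundCondition:
    if kind == "am":
        return SoundCondition("am", float(sound_tf))
    return SoundCondition(kind)


def _draw_rts(n: int, spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Truncated-lognormal response times in (MIN_RT, MAX_RT]."""
    mu, sig = math.log(spec.rt_median), math.log(spec.rt_gsd)
    rts = rng.lognormal(mu, sig, size=n)
    bad = (rts <= MIN_RT) | (rts > MAX_RT)
    while bad.any():
        rts[bad] = rng.lognormal(mu, sig, size=int(bad.sum()))
        bad = (rts <= MIN_RT) | (rts > MAX_RT)
    return rts


def simulate_cohort(
    spec: CohortSpec,
    stimset: StimulusSet | None = None,
    rng: np.random.Generator | None = None,
    return_params: bool = False,
):
    """Simulate a full cohort trial table.

    Visual-trial choices are Bernoulli draws from the psychometric function
    at the trial's intensity level; auditory-only choices are fair coin
    flips (rats show no sensitivity to the sound's temporal frequency).
    Returns the trial DataFrame, plus the per-rat true parameters when
    ``return_params`` is set.
    """
    stimset = stimset or StimulusSet()
    root = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(spec.seed)
    )
    frames = []
    true_params: dict[str, ObserverParams] = {}
    for r in range(spec.n_rats):
        rat_id = f"rat{r + 1:02d}"
        params = sample_rat_params(spec.population, root)
        true_params[rat_id] = params
        sched = build_schedule(spec, stimset, root)
        n = len(sched)
        level = np.array(
            [
                intensity_level_of(_sound_condition(k, t))
                for k, t in zip(sched["sound_kind"], sched["sound_tf_hz"])
            ]
        )
        p_high = np.full(n, 0.5)
        vmask = sched["visual_tf_hz"].notna().to_numpy()
        n_g = len(params.gamma)
        p_high[vmask] = [
            psychometric_s0(s, lv - 1 if n_g > 1 else 0, params, stimset.s0)
            for s, lv in zip(sched.loc[vmask, "visual_tf_hz"], level[vmask])
        ]
        choice = np.where(root.random(n) < p_high, "H", "L")
        out = sched.copy()
        out.insert(0, "rat_id", rat_id)
        out.insert(1, "session", np.arange(n) // spec.trials_per_session + 1)
        out["intensity_level"] = level
        out["choice"] = choice
        out["response_time_s"] = np.round(_draw_rts(n, spec, root), 6)
        frames.append(out.drop(columns=["category"]))
    trials = pd.concat(frames, ignore_index=True)[list(REQUIRED_COLUMNS)]
    if return_params:
        return trials, true_params
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-delimited text."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialSchemaError(f"missing required columns: {missing}")
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial table, validating schema and task timing constraints.

    Unknown columns are preserved; an empty file yields an empty table with
    the required columns; response times outside (0.3, 2.0] are rejected as
    aborted-trial violations.
    """
    try:
        trials = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialSchemaError(f"missing required columns: {missing}")
    rt = trials["response_time_s"]
    bad = rt.notna() & ((rt <= MIN_RT) | (rt > MAX_RT))
    if bad.any():
        raise TrialSchemaError(
            f"{int(bad.sum())} trials have response times outside "
            f"({MIN_RT}, {MAX_RT}] s (aborted or overtime trials)"
        )
    vt = trials["visual_tf_hz"].dropna()
    grid = np.asarray(StimulusSet().all_tfs)
    if len(vt) and not np.all(np.isclose(vt.to_numpy()[:, None], grid, atol=1e-9).any(axis=1)):
        raise TrialSchemaError("visual_tf_hz contains values outside the task grid")
    return trials
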