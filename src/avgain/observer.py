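"""Ideal-observer psychometric model with sound-dependent gain compression.

The observer forms a scalar Gaussian measurement of the grating's temporal
frequency and reports "High TF" when the measurement exceeds the decision
boundary learned in training.  With a linear encoding ``nu(s) = a + b*s``
the boundary is exactly the image of the category-boundary stimulus,
``x* = a + b*s0``, and the psychometric function is a probit in ``s``.
A concurrent sound multiplies the mean encoding by a gain ``gamma`` while
the boundary stays fixed, which for ``gamma < 1`` compresses the perceptual
axis and shifts choices toward the High category:

    p(H | s, n) = eps_H + (1 - eps_H - eps_L) *
                  Phi[(gamma_n * s - s0 + (gamma_n - 1) * lam) / sigma]

where ``sigma = rho / b`` is the sensory noise in stimulus units,
``lam = a / b`` the encoding offset (zero in the core model), and
``eps_H``/``eps_L`` stimulus-independent lapse rates bounding the curve
away from 0 and 1.

Besides the closed form, this module carries a brute-force generative
observer (explicit measurement draws plus the Bayes decision rule on the
9-component class mixture) used as an independent oracle for the closed
form in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtr

__all__ = [
    "StimulusSet",
    "ObserverParams",
    "GenerativeObserverConfig",
    "psychometric",
    "simulate_choice",
    "decision_boundary",
    "decision_boundary_numeric",
    "generative_oracle",
    "class_posterior",
    "PROB_FLOOR",
]

#: Probabilities are clipped to [PROB_FLOOR, 1 - PROB_FLOOR] before any
#: log-likelihood use, for numerical stability.
PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class StimulusSet:
    """The task's visual temporal-frequency grid.

    ``s0`` is the category boundary; ``low_tfs`` / ``high_tfs`` the K
    stimuli of each class, index-ordered symmetrically by distance from
    ``s0`` (the symmetry that pins the decision boundary at ``a + b*s0``).
    """

    s0: float = 2.12
    low_tfs: tuple[float, ...] = (0.25, 0.82, 1.32, 1.75)
    high_tfs: tuple[float, ...] = (2.48, 2.91, 3.41, 4.0)

    def __post_init__(self) -> None:
        if len(self.low_tfs) != len(self.high_tfs):
            raise ValueError("low and high classes must have equal size K")

    @property
    def K(self) -> int:
        return len(self.low_tfs)

    @classmethod
    def symmetric(
        cls, s0: float = 2.12,
        distances: Sequence[float] = (0.365, 0.795, 1.295, 1.875),
    ) -> "StimulusSet":
        """Exactly K-symmetric set: low = s0 - d, high = s0 + d.

        The task grid is symmetric on a log scale, so in linear stimulus
        space the class mixtures are only approximately mirror images; the
        boundary identity x* = a + b*s0 is exact only for a linearly
        symmetric set, which this constructor provides (default distances
        are the task grid's class-averaged offsets).
        """
        d = tuple(sorted(distances))
        return cls(
            s0=s0,
            low_tfs=tuple(s0 - x for x in d),
            high_tfs=tuple(s0 + x for x in d),
        )

    @property
    def all_tfs(self) -> tuple[float, ...]:
        """All stimuli in increasing order, boundary included."""
        return tuple(sorted((*self.low_tfs, self.s0, *self.high_tfs)))


@dataclass(frozen=True)
class ObserverParams:
    """Per-rat ideal-observer parameters.

    ``gamma`` holds one gain per sound-intensity level (or per condition);
    ``sigma`` is the sensory noise in Hz; ``eps_h``/``eps_l`` the lapse
    rates; ``lam`` the optional encoding-offset parameter (0 in the core
    model).
    """

    sigma: float
    gamma: tuple[float, ...]
    eps_h: float = 0.0
    eps_l: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("gamma factors must be positive")
        if self.eps_h < 0 or self.eps_l < 0 or self.eps_h + self.eps_l > 1:
            raise ValueError("lapse rates must be >= 0 with eps_h + eps_l <= 1")
        object.__setattr__(self, "gamma", tuple(float(g) for g in self.gamma))


@dataclass(frozen=True)
class GenerativeObserverConfig:
    """Reduced (a, b, rho) parameterisation of the measurement model.

    The neural encoding enters only through the projection intercept ``a``,
    slope ``b`` and total measurement noise ``rho``; ``n_mc`` is the number
    of Monte-Carlo measurement draws used by the generative oracle.
    """

    intercept_proj: float = 0.0
    slope_proj: float = 1.0
    rho: float = 0.5
    n_mc: int = 100_000

    def __post_init__(self) -> None:
        if self.slope_proj == 0:
            raise ValueError("projection slope must be nonzero")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def psychometric(s, level: int, params: ObserverParams):
    """Probability of reporting High TF for stimulus ``s`` at a sound level.

    Evaluates the lapse-extended probit with the level's gain; with
    ``lam = 0`` this is exactly the core model.  Output lies in
    ``[eps_h, 1 - eps_l]``.
    """
    g = params.gamma[level]
    s = np.asarray(s, dtype=float)
    z = (g * s - _S0_DEFAULT + (g - 1.0) * params.lam) / params.sigma
    p = params.eps_h + (1.0 - params.eps_h - params.eps_l) * ndtr(z)
    out = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(out) if out.ndim == 0 else out


_S0_DEFAULT = 2.12


def psychometric_s0(s, level: int, params: ObserverParams, s0: float):
    """As :func:`psychometric` but with an explicit category boundary."""
    g = params.gamma[level]
    s = np.asarray(s, dtype=float)
    z = (g * s - s0 + (g - 1.0) * params.lam) / params.sigma
    p = params.eps_h + (1.0 - params.eps_h - params.eps_l) * ndtr(z)
    out = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(out) if out.ndim == 0 else out


def simulate_choice(s, level: int, params: ObserverParams, rng: np.random.Generator):
    """Draw a choice ('H' or 'L') from the psychometric probability."""
    p = psychometric(s, level, params)
    draws = rng.random(np.shape(p))
    out = np.where(draws < p, "H", "L")
    return str(out[()]) if out.ndim == 0 else out


def decision_boundary(cfg: GenerativeObserverConfig, stimset: StimulusSet) -> float:
    """Closed-form decision boundary x* = a + b * s0."""
    return cfg.intercept_proj + cfg.slope_proj * stimset.s0


def class_posterior(x, cfg: GenerativeObserverConfig, stimset: StimulusSet):
    """Posterior probability of the High class given a measurement x.

    Uses the full class-conditional stimulus mixtures: each class is a
    (K+1)-component Gaussian mixture over measurements, sharing the boundary
    stimulus ``s0`` with weight 1/(2K+1) and giving weight 2/(2K+1) to each
    of its K own stimuli.
    """
    from scipy.special import logsumexp

    x = np.asarray(x, dtype=float)[..., None]
    a, b, rho = cfg.intercept_proj, cfg.slope_proj, cfg.rho
    K = stimset.K
    log_w_shared = math.log(1.0 / (2 * K + 1))
    log_w_own = math.log(2.0 / (2 * K + 1))

    def log_mix_like(tfs):
        mus = a + b * np.asarray([*tfs, stimset.s0], dtype=float)
        log_comps = -0.5 * ((x - mus) / rho) ** 2
        log_comps += np.array([log_w_own] * len(tfs) + [log_w_shared])
        return logsumexp(log_comps, axis=-1)

    log_h = log_mix_like(stimset.high_tfs)
    log_l = log_mix_like(stimset.low_tfs)
    # p(H|x) = 1 / (1 + exp(log_l - log_h)), stable at both extremes
    out = expit(log_h - log_l)
    return float(out) if out.ndim == 0 else out


def decision_boundary_numeric(
    cfg: GenerativeObserverConfig, stimset: StimulusSet, tol: float = 1e-12
) -> float:
    """Numeric boundary: root of p(H|x) - 1/2 via Brent bracketing.

    Independent check of the closed form; searches between the extreme
    component means.
    """
    a, b = cfg.intercept_proj, cfg.slope_proj
    tfs = stimset.all_tfs
    lo = a + b * min(tfs) - 5 * cfg.rho
    hi = a + b * max(tfs) + 5 * cfg.rho
    if lo > hi:
        lo, hi = hi, lo
    return brentq(lambda x: class_posterior(x, cfg, stimset) - 0.5, lo, hi, xtol=tol)


def generative_oracle(
    s: float,
    gamma: float,
    cfg: GenerativeObserverConfig,
    stimset: StimulusSet,
    rng: np.random.Generator,
) -> float:
    """Empirical probability of reporting High from explicit measurement draws.

    The sound scales the full mean encoding: measurements are drawn from
    ``Normal(gamma * (a + b*s), rho)`` and compared against the training
    boundary ``x* = a + b*s0``.  Equals the closed form with
    ``sigma = rho/b`` and ``lam = a/b`` up to Monte-Carlo error.
    """
    if cfg.n_mc < 10_000:
        raise ValueError("n_mc must be at least 10^4 for a usable oracle")
    mean = gamma * (cfg.intercept_proj + cfg.slope_proj * s)
    x = rng.normal(mean, cfg.rho, size=cfg.n_mc)
    x_star = decision_boundary(cfg, stimset)
    if cfg.slope_proj > 0:
        return float(np.mean(x > x_star))
    return float(np.mean(x < x_star))


def params_from_projection(
    cfg: GenerativeObserverConfig, gamma: Sequence[float] | float
) -> ObserverParams:
    """Translate an (a, b, rho) encoding into psychometric parameters.

    ``sigma = rho / b`` and ``lam = a / b`` — the exact reduction of the
    generative observer to the closed form.
    """
    g = (gamma,) if np.isscalar(gamma) else tuple(gamma)
    return ObserverParams(
        sigma=cfg.rho / abs(cfg.slope_proj),
        gamma=g,
        lam=cfg.intercept_proj / cfg.slope_proj,
    )
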