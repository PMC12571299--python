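"""Hierarchical Bayesian inference for the gain-compression observer.

The model ties per-rat observer parameters together through population
distributions:

    (eps_L, eps_H, 1 - eps_L - eps_H) ~ Dirichlet(1, 1, 1)        per rat
    sigma_r  ~ Gamma(shape k_sigma, scale theta_sigma)            per rat
    gamma_nr ~ Normal(mu_gamma_n, sd_gamma_n^2)                   per rat, level

with weakly informative hyperpriors

    mu_gamma_n  ~ Normal(0, 9)        sd_gamma_n ~ Exponential(scale 3)
    k_sigma     ~ Exponential(scale 3)   theta_sigma ~ Exponential(scale 3)

and the Bernoulli likelihood of the lapse-extended psychometric function.
Model variants: 1 or 5 sensitivities, 1/5/11 gains, an optional per-rat
encoding offset lambda with its own Normal/Exponential hierarchy, and a
variant whose level-wise gain means lie on a line in average sound level.

Sampling works on an unconstrained reparameterisation (log transforms for
positives, stick-breaking for the lapse simplex) and runs a bank of fully
independent Metropolis chains: after a Laplace-seeded adaptive warmup that
re-estimates the proposal mean and covariance from the pooled cross-chain
states, the frozen kernel alternates heavy-tailed independence proposals
with covariance-preconditioned random-walk steps.  The requested chains
are disjoint groups of those independent chains, so the cross-chain R-hat
diagnostic is exact; a differential-evolution ensemble sampler is kept as
an alternative method.

The public surface is statsmodels-like: build a
:class:`HierarchicalObserverModel` from a trial table, call :meth:`fit`,
and read estimates, diagnostics and predictive checks off the returned
:class:`HierarchicalObserverResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit, gammaln, logit, ndtr

from .acoustics import AM_FREQUENCIES, N_INTENSITY_LEVELS
from .cohort import LEVEL_INTENSITIES_DB
from .observer import PROB_FLOOR, ObserverParams, StimulusSet

__all__ = [
    "ModelSpec",
    "HierarchicalObserverModel",
    "HierarchicalObserverResults",
    "log_likelihood",
    "sample_posterior",
    "run_ensemble",
    "probability_of_direction",
]

# Canonical ordering of the 11 sound conditions for the per-condition model.
CONDITION_ORDER = ("silence", *(f"am_{f:g}Hz" for f in AM_FREQUENCIES), "fixed")


class SpecificationError(ValueError):
    """Raised when a model specification does not match the data."""


@dataclass(frozen=True)
class ModelSpec:
    """Which variant of the observer model to fit.

    ``n_sigma`` in {1, 5} and ``n_gamma`` in {1, 5, 11} select per-level (or
    per-condition) sensitivities and gains; ``include_lambda`` adds the
    hierarchical encoding-offset parameter; ``gamma_structure`` replaces the
    free level-wise gain means with a line in average sound intensity
    (``intensity_values`` in dB, one per level).
    """

    n_sigma: int = 1
    n_gamma: int = 5
    include_lambda: bool = False
    gamma_structure: str = "free"  # or "linear_in_intensity"
    intensity_values: tuple[float, ...] | None = None
    include_boundary_stimulus: bool = True

    def __post_init__(self) -> None:
        if self.n_sigma not in (1, 5):
            raise SpecificationError("n_sigma must be 1 or 5")
        if self.n_gamma not in (1, 5, 11):
            raise SpecificationError("n_gamma must be 1, 5 or 11")
        if self.gamma_structure not in ("free", "linear_in_intensity"):
            raise SpecificationError(f"unknown gamma_structure {self.gamma_structure!r}")
        if self.gamma_structure == "linear_in_intensity":
            if self.n_gamma != 5:
                raise SpecificationError("linear gamma structure requires n_gamma=5")
            if self.intensity_values is None:
                raise SpecificationError(
                    "linear gamma structure requires intensity_values (dB per level)"
                )
            if len(self.intensity_values) != N_INTENSITY_LEVELS:
                raise SpecificationError("one intensity value per level is required")
            object.__setattr__(
                self, "intensity_values",
                tuple(float(v) for v in self.intensity_values),
            )

    @property
    def name(self) -> str:
        parts = [f"{self.n_sigma}s{self.n_gamma}g"]
        if self.include_lambda:
            parts.append("1l")
        if self.gamma_structure == "linear_in_intensity":
            parts.append("lin")
        return "".join(parts)


def _softplus(x):
    return np.logaddexp(0.0, x)


def log_likelihood(
    params: ObserverParams,
    trials: pd.DataFrame,
    stimset: StimulusSet | None = None,
) -> np.ndarray:
    """Per-trial log probability of the observed choices for one rat.

    ``params.gamma`` must carry one gain per intensity level (or a single
    shared gain).  Trials without a visual stimulus are not part of the
    likelihood and raise.
    """
    stimset = stimset or StimulusSet()
    if trials["visual_tf_hz"].isna().any():
        bad = trials.index[trials["visual_tf_hz"].isna()].tolist()
        raise ValueError(f"trials without a visual stimulus in likelihood: {bad[:5]}")
    s = trials["visual_tf_hz"].to_numpy(dtype=float)
    lvl = trials["intensity_level"].to_numpy(dtype=int)
    gidx = lvl - 1 if len(params.gamma) > 1 else np.zeros(len(s), dtype=int)
    g = np.asarray(params.gamma)[gidx]
    z = (g * s - stimset.s0 + (g - 1.0) * params.lam) / params.sigma
    p = params.eps_h + (1.0 - params.eps_h - params.eps_l) * ndtr(z)
    p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    is_h = trials["choice"].to_numpy() == "H"
    return np.where(is_h, np.log(p), np.log1p(-p))


class HierarchicalObserverModel:
    """Hierarchical ideal-observer model bound to a trial table.

    Parameters
    ----------
    trials : DataFrame
        Trial table with the standard columns.  Auditory-only trials and
        trials with missing response times are excluded from the likelihood
        (the count is kept in ``n_excluded``).
    spec : ModelSpec
        Model variant to fit.
    stimset : StimulusSet, optional
        Task stimulus grid; defaults to the nine-frequency design.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        spec: ModelSpec | None = None,
        stimset: StimulusSet | None = None,
    ):
        self.spec = spec or ModelSpec()
        self.stimset = stimset or StimulusSet()
        full = trials.reset_index(drop=True)
        keep = full["visual_tf_hz"].notna() & full["response_time_s"].notna()
        if not self.spec.include_boundary_stimulus:
            keep &= ~np.isclose(full["visual_tf_hz"].astype(float), self.stimset.s0)
        self.trials = full.loc[keep].reset_index(drop=True)
        self.n_excluded = int(len(full) - len(self.trials))
        if self.trials.empty:
            raise SpecificationError("no usable trials for the likelihood")
        self.rats = tuple(pd.unique(self.trials["rat_id"]))
        self._build_design()
        self._build_layout()

    # ------------------------------------------------------------------ design
    def _gamma_index(self, trials: pd.DataFrame) -> np.ndarray:
        if self.spec.n_gamma == 1:
            return np.zeros(len(trials), dtype=int)
        if self.spec.n_gamma == 5:
            return trials["intensity_level"].to_numpy(dtype=int) - 1
        labels = np.where(
            trials["sound_kind"] == "am",
            "am_" + trials["sound_tf_hz"].map(lambda v: f"{v:g}") + "Hz",
            trials["sound_kind"].astype(str),
        )
        lut = {lab: i for i, lab in enumerate(CONDITION_ORDER)}
        try:
            return np.array([lut[l] for l in labels])
        except KeyError as e:  # pragma: no cover - schema guarded upstream
            raise SpecificationError(f"unknown sound condition {e}") from None

    def _sigma_index(self, trials: pd.DataFrame) -> np.ndarray:
        if self.spec.n_sigma == 1:
            return np.zeros(len(trials), dtype=int)
        return trials["intensity_level"].to_numpy(dtype=int) - 1

    def _build_design(self) -> None:
        t = self.trials
        rat_lut = {r: i for i, r in enumerate(self.rats)}
        rat = t["rat_id"].map(rat_lut).to_numpy()
        gidx = self._gamma_index(t)
        sidx = self._sigma_index(t)
        if self.spec.n_gamma == 5 or self.spec.n_sigma == 5:
            lv = t["intensity_level"].to_numpy(dtype=float)
            if np.isnan(lv).any():
                raise SpecificationError("intensity_level missing on visual trials")
        s = t["visual_tf_hz"].to_numpy(dtype=float)
        key = pd.DataFrame({"rat": rat, "s": s, "g": gidx, "sg": sidx})
        cells, cell_of_trial = np.unique(
            key.to_numpy(), axis=0, return_inverse=True
        )
        self.cell_rat = cells[:, 0].astype(int)
        self.cell_s = cells[:, 1].astype(float)
        self.cell_g = cells[:, 2].astype(int)
        self.cell_sg = cells[:, 3].astype(int)
        self.trial_cell = cell_of_trial
        self.trial_is_h = (t["choice"].to_numpy() == "H")
        n_cells = len(self.cell_s)
        self.cell_n = np.bincount(cell_of_trial, minlength=n_cells).astype(float)
        self.cell_k = np.bincount(
            cell_of_trial, weights=self.trial_is_h, minlength=n_cells
        ).astype(float)
        self.n_trials = len(t)

    # ------------------------------------------------------------------ layout
    def _build_layout(self) -> None:
        spec, R = self.spec, len(self.rats)
        G = spec.n_gamma
        self.G, self.Ns, self.R = G, spec.n_sigma, R
        layout: list[tuple[str, int]] = []
        if spec.gamma_structure == "free":
            layout += [("mu_gamma", G), ("log_sd_gamma", G)]
        else:
            layout += [("gamma_intercept", 1), ("gamma_slope", 1), ("log_sd_gamma", 1)]
        layout += [("log_k_sigma", 1), ("log_theta_sigma", 1)]
        if spec.include_lambda:
            layout += [("mu_lambda", 1), ("log_sd_lambda", 1)]
        layout += [
            ("eps_raw", 2 * R),
            ("log_sigma", spec.n_sigma * R),
            ("gamma_raw", G * R),
        ]
        if spec.include_lambda:
            layout += [("lam_raw", R)]
        self._slices: dict[str, slice] = {}
        off = 0
        for name, size in layout:
            self._slices[name] = slice(off, off + size)
            off += size
        self.n_params = off

    def _unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.atleast_2d(theta)
        out = {k: theta[:, sl] for k, sl in self._slices.items()}
        W, R, G = theta.shape[0], self.R, self.G
        out["eps_raw"] = out["eps_raw"].reshape(W, R, 2)
        out["log_sigma"] = out["log_sigma"].reshape(W, R, self.Ns)
        out["gamma_raw"] = out["gamma_raw"].reshape(W, R, G)
        return out

    # --------------------------------------------------------------- log prob
    def _constrained(self, pars: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Map unconstrained parameters to model space (vectorised over walkers)."""
        spec = self.spec
        out: dict[str, np.ndarray] = {}
        sd_gamma = np.exp(np.clip(pars["log_sd_gamma"], -300, 300))
        if spec.gamma_structure == "free":
            mu_gamma = pars["mu_gamma"]
        else:
            iv = np.asarray(spec.intensity_values)
            mu_gamma = (
                pars["gamma_intercept"] + pars["gamma_slope"] * iv[None, :]
            )
            sd_gamma = np.repeat(sd_gamma, self.G, axis=1)
        out["mu_gamma"] = mu_gamma
        out["sd_gamma"] = sd_gamma
        out["k_sigma"] = np.exp(np.clip(pars["log_k_sigma"], -300, 300))
        out["theta_sigma"] = np.exp(np.clip(pars["log_theta_sigma"], -300, 300))
        v = expit(pars["eps_raw"])  # (W, R, 2)
        eps_l = v[..., 0]
        eps_h = (1.0 - v[..., 0]) * v[..., 1]
        out["eps_l"], out["eps_h"] = eps_l, eps_h
        out["sigma"] = np.exp(np.clip(pars["log_sigma"], -300, 300))  # (W, R, Ns)
        out["gamma"] = pars["gamma_raw"]
        if spec.include_lambda:
            out["mu_lambda"] = pars["mu_lambda"][:, 0]
            out["sd_lambda"] = np.exp(np.clip(pars["log_sd_lambda"][:, 0], -300, 300))
            out["lam"] = pars["lam_raw"]
        else:
            out["lam"] = None
        return out

    def _log_prior(self, pars, con) -> np.ndarray:
        spec = self.spec
        lp = np.zeros(con["k_sigma"].shape[0])
        # hyperpriors
        if spec.gamma_structure == "free":
            lp += -0.5 * np.sum(pars["mu_gamma"] ** 2, axis=1) / 9.0
        else:
            lp += -0.5 * (pars["gamma_intercept"][:, 0] ** 2) / 9.0
            lp += -0.5 * (pars["gamma_slope"][:, 0] ** 2) / 9.0
        sdg = np.exp(np.clip(pars["log_sd_gamma"], -300, 300))
        lp += np.sum(-sdg / 3.0 + pars["log_sd_gamma"], axis=1)
        for nm in ("log_k_sigma", "log_theta_sigma"):
            val = np.exp(np.clip(pars[nm][:, 0], -300, 300))
            lp += -val / 3.0 + pars[nm][:, 0]
        if spec.include_lambda:
            lp += -0.5 * (pars["mu_lambda"][:, 0] ** 2) / 9.0
            sdl = con["sd_lambda"]
            lp += -sdl / 3.0 + pars["log_sd_lambda"][:, 0]
            resid_l = (pars["lam_raw"] - con["mu_lambda"][:, None]) / sdl[:, None]
            lp += -0.5 * np.sum(resid_l**2, axis=1) - self.R * np.log(sdl)
        # lapse simplex: uniform Dirichlet + stick-breaking Jacobian
        z = pars["eps_raw"]  # (W, R, 2)
        lp += np.sum(
            -_softplus(-z[..., 0]) - 2.0 * _softplus(z[..., 0])
            - _softplus(-z[..., 1]) - _softplus(z[..., 1]),
            axis=1,
        )
        # sigma ~ Gamma(k, theta) with log Jacobian
        k = con["k_sigma"][:, 0][:, None, None]
        th = con["theta_sigma"][:, 0][:, None, None]
        sig, logsig = con["sigma"], pars["log_sigma"]
        lp += np.sum(
            (k - 1.0) * logsig - sig / th - k * np.log(th) - gammaln(k) + logsig,
            axis=(1, 2),
        )
        # centred gains: gamma_nr ~ Normal(mu_gamma_n, sd_gamma_n^2)
        resid = (con["gamma"] - con["mu_gamma"][:, None, :]) / con["sd_gamma"][:, None, :]
        lp += -0.5 * np.sum(resid**2, axis=(1, 2))
        lp += -self.R * np.sum(np.log(con["sd_gamma"]), axis=1)
        return lp

    def _cell_prob(self, con) -> np.ndarray:
        """Per-cell probability of an H choice, shape (W, n_cells)."""
        g = con["gamma"][:, self.cell_rat, self.cell_g]
        sig = con["sigma"][:, self.cell_rat, self.cell_sg if self.Ns > 1 else 0]
        eh = con["eps_h"][:, self.cell_rat]
        el = con["eps_l"][:, self.cell_rat]
        lam = 0.0 if con["lam"] is None else con["lam"][:, self.cell_rat]
        z = (g * self.cell_s - self.stimset.s0 + (g - 1.0) * lam) / sig
        p = eh + (1.0 - eh - el) * ndtr(z)
        return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalised log posterior, vectorised over a walker batch."""
        theta = np.atleast_2d(theta)
        pars = self._unpack(theta)
        con = self._constrained(pars)
        lp = self._log_prior(pars, con)
        p = self._cell_prob(con)
        ll = self.cell_k @ np.log(p).T + (self.cell_n - self.cell_k) @ np.log1p(-p).T
        out = lp + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log likelihood for a batch of parameter vectors (W, N)."""
        con = self._constrained(self._unpack(theta))
        p = self._cell_prob(con)[:, self.trial_cell]
        return np.where(self.trial_is_h, np.log(p), np.log1p(-p))

    # ------------------------------------------------------------------- init
    def _empirical_start(self) -> np.ndarray:
        """Data-informed starting point via probit regression per rat."""
        from scipy.special import ndtri

        t, s0 = self.trials, self.stimset.s0
        x0 = np.zeros(self.n_params)
        mu_g = np.ones(self.G)
        sigmas, gammas = [], []
        for ri, rat in enumerate(self.rats):
            sub = t[t["rat_id"] == rat]
            prop = sub.groupby("visual_tf_hz")["choice"].apply(lambda c: (c == "H").mean())
            z = ndtri(np.clip(prop.to_numpy(), 0.02, 0.98))
            s = prop.index.to_numpy(dtype=float)
            if len(s) >= 2 and np.ptp(s) > 0:
                slope, inter = np.polyfit(s, z, 1)
                slope = max(slope, 0.05)
                sigma = float(np.clip(-s0 / min(inter, -1e-3), 0.1, 5.0)) if inter < 0 else 1.0
                gamma = float(np.clip(slope * sigma, 0.2, 3.0))
            else:
                sigma, gamma = 1.0, 1.0
            sigmas.append(sigma)
            gammas.append(gamma)
        sig_mean = float(np.mean(sigmas))
        mu_g[:] = float(np.mean(gammas))
        sl = self._slices
        if self.spec.gamma_structure == "free":
            x0[sl["mu_gamma"]] = mu_g
        else:
            x0[sl["gamma_intercept"]] = np.mean(gammas)
            x0[sl["gamma_slope"]] = 0.0
        x0[sl["log_sd_gamma"]] = math.log(0.15)
        x0[sl["log_k_sigma"]] = math.log(4.0)
        x0[sl["log_theta_sigma"]] = math.log(max(sig_mean, 0.05) / 4.0)
        x0[sl["eps_raw"]] = logit(0.08)
        x0[sl["log_sigma"]] = np.repeat(np.log(sigmas), self.Ns)
        x0[sl["gamma_raw"]] = np.repeat(np.asarray(gammas), self.G)
        if self.spec.include_lambda:
            x0[sl["mu_lambda"]] = 0.0
            x0[sl["log_sd_lambda"]] = math.log(0.1)
        return x0

    # ---------------------------------------------------------- MAP / Laplace
    def _phi_to_theta(self, phi: np.ndarray) -> np.ndarray:
        """Map auxiliary non-centred coordinates to the sampling coordinates.

        In the auxiliary space the gain block holds standardised offsets z
        with gamma = mu + sd * z (likewise for lambda), which removes the
        funnel spike at sd -> 0 so the posterior mode is interior there.
        """
        phi = np.atleast_2d(phi)
        theta = phi.copy()
        pars = {k: phi[:, sl] for k, sl in self._slices.items()}
        W = phi.shape[0]
        sd_gamma = np.exp(np.clip(pars["log_sd_gamma"], -300, 300))
        if self.spec.gamma_structure == "free":
            mu_gamma = pars["mu_gamma"]
        else:
            iv = np.asarray(self.spec.intensity_values)
            mu_gamma = pars["gamma_intercept"] + pars["gamma_slope"] * iv[None, :]
            sd_gamma = np.repeat(sd_gamma, self.G, axis=1)
        z = pars["gamma_raw"].reshape(W, self.R, self.G)
        gamma = mu_gamma[:, None, :] + sd_gamma[:, None, :] * z
        theta[:, self._slices["gamma_raw"]] = gamma.reshape(W, -1)
        if self.spec.include_lambda:
            sdl = np.exp(np.clip(pars["log_sd_lambda"], -300, 300))
            theta[:, self._slices["lam_raw"]] = (
                pars["mu_lambda"] + sdl * pars["lam_raw"]
            )
        return theta

    def _log_prob_nc(self, phi: np.ndarray) -> np.ndarray:
        """Log posterior in the auxiliary non-centred coordinates."""
        phi = np.atleast_2d(phi)
        lp = self.log_prob(self._phi_to_theta(phi))
        # log |d theta / d phi| = R * sum_n log sd_n (+ R log sd_lambda)
        logsd = np.clip(phi[:, self._slices["log_sd_gamma"]], -300, 300)
        mult = self.G if self.spec.gamma_structure != "free" else 1
        lp = lp + self.R * mult * logsd.sum(axis=1)
        if self.spec.include_lambda:
            lp = lp + self.R * np.clip(
                phi[:, self._slices["log_sd_lambda"]], -300, 300
            ).sum(axis=1)
        return lp

    def _neg_nc_logprob_and_grad(self, x: np.ndarray):
        """Objective and central-difference gradient in one batched call."""
        D = self.n_params
        h = 1e-5 * (1.0 + np.abs(x))
        X = np.vstack([x[None, :], x + np.diag(h), x - np.diag(h)])
        lp = self._log_prob_nc(X)
        grad = (lp[1:D + 1] - lp[D + 1:]) / (2.0 * h)
        return -lp[0], -grad

    def _nc_start(self) -> np.ndarray:
        """Empirical start expressed in the auxiliary coordinates."""
        x0 = self._empirical_start()
        phi = x0.copy()
        sl = self._slices
        sd = np.exp(x0[sl["log_sd_gamma"]])
        if self.spec.gamma_structure == "free":
            mu = x0[sl["mu_gamma"]]
        else:
            iv = np.asarray(self.spec.intensity_values)
            mu = x0[sl["gamma_intercept"]] + x0[sl["gamma_slope"]] * iv
            sd = np.repeat(sd, self.G)
        gam = x0[sl["gamma_raw"]].reshape(self.R, self.G)
        phi[sl["gamma_raw"]] = ((gam - mu) / sd).ravel()
        if self.spec.include_lambda:
            sdl = np.exp(x0[sl["log_sd_lambda"]])
            phi[sl["lam_raw"]] = (
                x0[sl["lam_raw"]] - x0[sl["mu_lambda"]]
            ) / sdl
        return phi

    def find_map(self, maxiter: int = 500):
        """Posterior mode and Laplace covariance in the sampling coordinates.

        The mode is located in the auxiliary non-centred space (interior
        there), and mode and curvature are pushed through the
        auxiliary-to-sampling transform; the covariance uses the transform's
        Jacobian at the mode.
        """
        from scipy.optimize import minimize

        res = minimize(
            self._neg_nc_logprob_and_grad, self._nc_start(), jac=True,
            method="L-BFGS-B", options={"maxiter": maxiter, "maxcor": 25},
        )
        phi_map = res.x
        cov_phi = self._laplace_cov(phi_map, logprob=self._log_prob_nc)
        # numeric Jacobian of the (cheap, pure-numpy) transform
        D = self.n_params
        h = 1e-6 * (1.0 + np.abs(phi_map))
        X = np.vstack([phi_map + np.diag(h), phi_map - np.diag(h)])
        T = self._phi_to_theta(X)
        J = ((T[:D] - T[D:]) / (2.0 * h)[:, None]).T
        theta_map = self._phi_to_theta(phi_map[None, :])[0]
        cov_theta = J @ cov_phi @ J.T
        return theta_map, 0.5 * (cov_theta + cov_theta.T)

    def _laplace_cov(self, xmap: np.ndarray, logprob=None, chunk: int = 4096) -> np.ndarray:
        """Covariance of the Laplace approximation at the mode.

        Negative-Hessian of the log posterior by batched central finite
        differences, symmetrised, with an eigenvalue floor so the result is
        always a valid covariance.
        """
        logprob = logprob or self.log_prob
        D = self.n_params
        h = 1e-3 * (1.0 + np.abs(xmap))
        pts = [xmap[None, :]]
        for i in range(D):
            ei = np.zeros(D); ei[i] = h[i]
            pts.append(xmap[None, :] + ei)
            pts.append(xmap[None, :] - ei)
        pairs = [(i, j) for i in range(D) for j in range(i + 1, D)]
        for i, j in pairs:
            eij = np.zeros(D); eij[i] = h[i]; eij[j] = h[j]
            eij2 = np.zeros(D); eij2[i] = h[i]; eij2[j] = -h[j]
            pts.append(xmap[None, :] + eij)
            pts.append(xmap[None, :] - eij)
            pts.append(xmap[None, :] + eij2)
            pts.append(xmap[None, :] - eij2)
        X = np.vstack(pts)
        lp = np.concatenate(
            [logprob(X[k:k + chunk]) for k in range(0, len(X), chunk)]
        )
        lp0 = lp[0]
        H = np.empty((D, D))
        for i in range(D):
            H[i, i] = (lp[1 + 2 * i] - 2 * lp0 + lp[2 + 2 * i]) / h[i] ** 2
        off = 1 + 2 * D
        for idx, (i, j) in enumerate(pairs):
            p4 = lp[off + 4 * idx: off + 4 * idx + 4]
            H[i, j] = H[j, i] = (p4[0] + p4[1] - p4[2] - p4[3]) / (4 * h[i] * h[j])
        A = -0.5 * (H + H.T)  # negative Hessian, symmetrised
        w, V = np.linalg.eigh(A)
        floor = max(w.max(), 1.0) * 1e-8
        w = np.clip(w, floor, None)
        return (V / w) @ V.T

    # -------------------------------------------------------------------- fit
    def fit(
        self,
        chains: int = 4,
        tune: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        method: str = "laplace_mh",
        thin: int = 20,
        n_mh_chains: int = 128,
        proposal_df: float = 4.0,
        proposal_scale: float = 1.0,
        n_walkers: int | None = None,
        store_loglik: bool = True,
        progress: bool = False,
    ) -> "HierarchicalObserverResults":
        """Sample the posterior and return a results object.

        The default sampler runs a bank of fully independent Metropolis
        chains, warmed up in adaptation windows: the proposal starts from a
        Laplace approximation at the posterior mode and is repeatedly
        re-estimated from the pooled cross-chain states (mean and
        covariance), after which the kernel is frozen and draws are
        collected.  The frozen kernel alternates an independence proposal
        (heavy-tailed multivariate t at the adapted mean, giving large
        decorrelating jumps) with a covariance-preconditioned random walk
        (local exploration wherever the Gaussian summary is imperfect).
        The requested ``chains`` are disjoint groups of the independent
        chains, so the cross-chain R-hat diagnostic is exact.
        ``method="ensemble"`` uses affine-invariant/differential-evolution
        ensemble MCMC instead (slower mixing, no mode-finding step).
        """
        if method == "ensemble":
            return self._fit_ensemble(
                chains, tune, draws, seed, max(thin, 10), n_walkers, store_loglik,
                progress,
            )
        from scipy.linalg import solve_triangular

        D = self.n_params
        m = max(2, n_mh_chains // chains)
        M = m * chains
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1A91]))
        center, cov = self.find_map()

        def make_kernel(center, cov, rw_step):
            ridge = 1e-10 * np.trace(cov) / D + 1e-300
            Lc = np.linalg.cholesky(cov + ridge * np.eye(D))

            def propose_imh(n):
                z = rng.standard_normal((n, D))
                g = rng.chisquare(proposal_df, size=n) / proposal_df
                return center[None, :] + proposal_scale * (z @ Lc.T) / np.sqrt(g)[:, None]

            def logq(X):
                # unnormalised multivariate-t log density
                d = solve_triangular(
                    Lc, (X - center[None, :]).T / proposal_scale, lower=True
                )
                msq = np.sum(d * d, axis=0)
                return -0.5 * (proposal_df + D) * np.log1p(msq / proposal_df)

            def propose_rw(X):
                return X + rw_step * (rng.standard_normal((X.shape[0], D)) @ Lc.T)

            return propose_imh, logq, propose_rw

        rw_step = 2.38 / math.sqrt(D)
        propose_imh, logq, propose_rw = make_kernel(center, cov, rw_step)

        # start tight around the mode; adaptation spreads the bank out
        X = center[None, :] + 0.3 * propose_rw(np.zeros((M, D)))
        lpX = self.log_prob(X)
        bad = ~np.isfinite(lpX)
        if bad.any():
            X[bad] = center
            lpX[bad] = self.log_prob(center[None, :])[0]
        lqX = logq(X)

        def run_steps(n_steps, collect_every=0, K=0):
            nonlocal X, lpX, lqX
            snaps = np.empty((K, M, D)) if K else None
            snap_lp = np.empty((K, M)) if K else None
            acc_counts = np.zeros(2)
            prop_counts = np.zeros(2)
            buffer = []
            k = 0
            for step in range(1, n_steps + 1):
                kind = step % 2  # 1: independence move, 0: random walk
                if kind:
                    Y = propose_imh(M)
                    lpY = self.log_prob(Y)
                    lqY = logq(Y)
                    log_alpha = (lpY - lqY) - (lpX - lqX)
                else:
                    Y = propose_rw(X)
                    lpY = self.log_prob(Y)
                    lqY = logq(Y)
                    log_alpha = lpY - lpX
                accept = np.log(rng.random(M)) < log_alpha
                X[accept] = Y[accept]
                lpX[accept] = lpY[accept]
                lqX[accept] = lqY[accept]
                acc_counts[kind] += accept.sum()
                prop_counts[kind] += M
                if collect_every and step % collect_every == 0:
                    buffer.append(X.copy())
                if K and step % collect_every == 0 and k < K:
                    snaps[k] = X
                    snap_lp[k] = lpX
                    k += 1
            return snaps, snap_lp, acc_counts / np.maximum(prop_counts, 1), buffer

        # ---- adaptation windows (all states discarded) -----------------
        n_windows = 4
        window = max(50, tune // n_windows)
        for w in range(n_windows):
            _, _, acc_kinds, buf = run_steps(window, collect_every=5)
            pooled = np.concatenate(buf, axis=0)
            new_center = pooled.mean(axis=0)
            new_cov = np.cov(pooled, rowvar=False)
            if not np.all(np.isfinite(new_cov)):
                new_cov = cov
            # blend with the previous estimate for stability
            center = 0.5 * center + 0.5 * new_center
            cov = 0.5 * cov + 0.5 * (new_cov + 1e-12 * np.eye(D))
            rw_acc = acc_kinds[0]
            rw_step = float(np.clip(rw_step * math.exp(rw_acc - 0.25), 1e-3, 5.0))
            propose_imh, logq, propose_rw = make_kernel(center, cov, rw_step)
            lqX = logq(X)

        # ---- frozen kernel: short equilibration, then collection -------
        K = math.ceil(draws / m)
        run_steps(max(100, tune // 4))
        snaps, snap_lp, acc_kinds, _ = run_steps(K * thin, collect_every=thin, K=K)
        post = np.empty((chains, draws, D))
        lp_stat = np.empty((chains, draws))
        for c in range(chains):
            sub = snaps[:, c * m:(c + 1) * m, :].reshape(K * m, D)
            post[c] = sub[:draws]
            lp_stat[c] = snap_lp[:, c * m:(c + 1) * m].reshape(K * m)[:draws]
        acc = np.full(chains, float(acc_kinds.mean()))
        loglik = self._compute_loglik(post) if store_loglik else None
        idata = self._to_inference_data(post, lp_stat, loglik)
        return HierarchicalObserverResults(
            model=self, idata=idata, acceptance_fraction=acc, map_estimate=center,
        )

    def _fit_ensemble(
        self, chains, tune, draws, seed, thin, n_walkers, store_loglik, progress
    ) -> "HierarchicalObserverResults":
        D = self.n_params
        W = n_walkers or max(2 * (D + 1), 64)
        W += W % 2
        chain_seeds = np.random.SeedSequence([seed, 0x5EED]).spawn(chains)
        x0 = self._empirical_start()
        post = np.empty((chains, draws, D))
        acc = np.empty(chains)
        lp_stat = np.empty((chains, draws))
        keep_steps = max(1, math.ceil(draws / W))
        for c in range(chains):
            rng = np.random.default_rng(chain_seeds[c])
            init = x0[None, :] + 0.05 * rng.standard_normal((W, D))
            sampler = emcee.EnsembleSampler(
                W, D, self.log_prob, vectorize=True,
                moves=[(emcee.moves.DEMove(), 0.8),
                       (emcee.moves.DESnookerMove(), 0.2)],
            )
            sampler._random = np.random.RandomState(
                int(chain_seeds[c].generate_state(1)[0] % (2**31))
            )
            sampler.run_mcmc(
                init, tune + keep_steps * thin, progress=progress,
                skip_initial_state_check=True,
            )
            chain = sampler.get_chain(discard=tune, thin=thin)  # (keep, W, D)
            logp = sampler.get_log_prob(discard=tune, thin=thin)
            post[c] = chain.reshape(-1, D)[:draws]
            lp_stat[c] = logp.reshape(-1)[:draws]
            acc[c] = float(np.mean(sampler.acceptance_fraction))
        loglik = self._compute_loglik(post) if store_loglik else None
        idata = self._to_inference_data(post, lp_stat, loglik)
        return HierarchicalObserverResults(
            model=self, idata=idata, acceptance_fraction=acc,
        )

    def _compute_loglik(self, post: np.ndarray) -> np.ndarray:
        chains, draws, _ = post.shape
        loglik = np.empty((chains, draws, self.n_trials))
        for c in range(chains):
            for start in range(0, draws, 200):
                blk = post[c, start:start + 200]
                loglik[c, start:start + 200] = self.pointwise_loglik(blk)
        return loglik

    # -------------------------------------------------------------- packaging
    def _to_inference_data(self, post, lp_stat, loglik) -> az.InferenceData:
        chains, draws, _ = post.shape
        pars = self._unpack(post.reshape(-1, self.n_params))
        con = self._constrained(pars)

        def cd(a, extra=()):
            return a.reshape(chains, draws, *extra)

        R, G, Ns = self.R, self.G, self.Ns
        coords = {
            "rat": list(self.rats),
            "gamma_dim": (
                list(CONDITION_ORDER) if G == 11
                else [f"level{i+1}" for i in range(G)]
            ),
            "sigma_dim": [f"level{i+1}" for i in range(Ns)] if Ns > 1 else ["all"],
        }
        posterior = {
            "mu_gamma": (["gamma_dim"], cd(con["mu_gamma"], (G,))),
            "sd_gamma": (["gamma_dim"], cd(con["sd_gamma"], (G,))),
            "k_sigma": ([], cd(con["k_sigma"][:, 0])),
            "theta_sigma": ([], cd(con["theta_sigma"][:, 0])),
            "gamma": (["rat", "gamma_dim"], cd(con["gamma"], (R, G))),
            "sigma": (["rat", "sigma_dim"], cd(con["sigma"], (R, Ns))),
            "eps_h": (["rat"], cd(con["eps_h"], (R,))),
            "eps_l": (["rat"], cd(con["eps_l"], (R,))),
        }
        if self.spec.gamma_structure == "linear_in_intensity":
            posterior["gamma_intercept"] = ([], cd(pars["gamma_intercept"][:, 0]))
            posterior["gamma_slope"] = ([], cd(pars["gamma_slope"][:, 0]))
        if self.spec.include_lambda:
            posterior["mu_lambda"] = ([], cd(con["mu_lambda"]))
            posterior["sd_lambda"] = ([], cd(con["sd_lambda"]))
            posterior["lam"] = (["rat"], cd(con["lam"], (R,)))
        post_ds = xr.Dataset(
            {
                k: xr.DataArray(v, dims=("chain", "draw", *dims))
                for k, (dims, v) in posterior.items()
            },
            coords={k: np.asarray(v) for k, v in coords.items()},
        )
        groups = {
            "posterior": post_ds,
            "sample_stats": xr.Dataset(
                {"lp": xr.DataArray(lp_stat, dims=("chain", "draw"))}
            ),
        }
        if loglik is not None:
            groups["log_likelihood"] = xr.Dataset(
                {"choice": xr.DataArray(loglik, dims=("chain", "draw", "trial"))}
            )
        return az.InferenceData(**groups)

    # -------------------------------------------------- helpers for validation
    def theta_from_params(
        self,
        rat_params: Mapping[str, ObserverParams],
        mu_gamma: Sequence[float] | None = None,
        sd_gamma: Sequence[float] | None = None,
        k_sigma: float = 4.0,
        theta_sigma: float = 0.25,
    ) -> np.ndarray:
        """Pack explicit per-rat parameters into an unconstrained vector."""
        sl = self._slices
        x = np.zeros(self.n_params)
        G = self.G
        mu = np.asarray(mu_gamma if mu_gamma is not None else np.ones(G), dtype=float)
        sd = np.asarray(sd_gamma if sd_gamma is not None else 0.2 * np.ones(G), dtype=float)
        if self.spec.gamma_structure != "free":
            raise SpecificationError("packing is only supported for the free model")
        x[sl["mu_gamma"]] = mu
        x[sl["log_sd_gamma"]] = np.log(sd)
        x[sl["log_k_sigma"]] = math.log(k_sigma)
        x[sl["log_theta_sigma"]] = math.log(theta_sigma)
        eps = np.zeros((self.R, 2))
        logsig = np.zeros((self.R, self.Ns))
        zg = np.zeros((self.R, G))
        zl = np.zeros(self.R)
        for ri, rat in enumerate(self.rats):
            p = rat_params[rat]
            v1 = np.clip(p.eps_l, 1e-9, 1 - 1e-9)
            v2 = np.clip(p.eps_h / max(1.0 - p.eps_l, 1e-9), 1e-9, 1 - 1e-9)
            eps[ri] = [logit(v1), logit(v2)]
            logsig[ri] = math.log(p.sigma)
            gam = np.asarray(p.gamma, dtype=float)
            if len(gam) != G:
                gam = np.full(G, gam[0])
            zg[ri] = gam
            zl[ri] = p.lam
        x[sl["eps_raw"]] = eps.ravel()
        x[sl["log_sigma"]] = logsig.ravel()
        x[sl["gamma_raw"]] = zg.ravel()
        if self.spec.include_lambda:
            x[sl["mu_lambda"]] = 0.0
            x[sl["log_sd_lambda"]] = math.log(0.1)
            x[sl["lam_raw"]] = zl
        return x


# ----------------------------------------------------------------- results
HYPER_VARS = ("mu_gamma", "sd_gamma", "k_sigma", "theta_sigma",
              "mu_lambda", "sd_lambda", "gamma_intercept", "gamma_slope")


class HierarchicalObserverResults:
    """Posterior samples plus diagnostics for a fitted observer model."""

    def __init__(self, model, idata, acceptance_fraction, map_estimate=None):
        self.model = model
        self.idata = idata
        self.acceptance_fraction = np.asarray(acceptance_fraction)
        self.map_estimate = map_estimate
        self._summary = None

    def summary(self, var_names: Sequence[str] | None = None) -> pd.DataFrame:
        """Posterior summary table (mean, sd, HDI 3/97%, MCSE, ESS, R-hat)."""
        if var_names is None:
            var_names = [v for v in HYPER_VARS if v in self.idata.posterior]
        return az.summary(self.idata, var_names=list(var_names), hdi_prob=0.94)

    @property
    def converged(self) -> bool:
        """True when every hyperparameter R-hat is at most 1.01."""
        s = self.summary()
        return bool((s["r_hat"] <= 1.01).all())

    @property
    def max_rhat(self) -> float:
        return float(self.summary()["r_hat"].max())

    @property
    def min_ess_bulk(self) -> float:
        return float(self.summary()["ess_bulk"].min())

    def posterior_interval(self, var: str, prob: float = 0.95) -> pd.DataFrame:
        """Central credible interval per coordinate of a posterior variable."""
        da = self.idata.posterior[var]
        lo = da.quantile(0.5 * (1 - prob), dim=("chain", "draw"))
        hi = da.quantile(1 - 0.5 * (1 - prob), dim=("chain", "draw"))
        mean = da.mean(dim=("chain", "draw"))
        extra = [d for d in da.dims if d not in ("chain", "draw")]
        return pd.DataFrame(
            {
                "mean": np.atleast_1d(mean.values.ravel()),
                "lower": np.atleast_1d(lo.values.ravel()),
                "upper": np.atleast_1d(hi.values.ravel()),
            },
            index=(
                [str(c) for c in da.coords[extra[0]].values] if extra else [var]
            ),
        )

    def probability_of_direction(self, var: str, coord: Mapping | None = None):
        """Probability of direction of a scalar posterior quantity."""
        da = self.idata.posterior[var]
        if coord:
            da = da.sel(**coord)
        return probability_of_direction(da.values.ravel())

    def pointwise_loglik_array(self) -> np.ndarray:
        """(chains*draws, n_trials) pointwise log-likelihood matrix."""
        ll = self.idata.log_likelihood["choice"].values
        return ll.reshape(-1, ll.shape[-1])


def probability_of_direction(samples: np.ndarray) -> tuple[float, float]:
    """Fraction of posterior mass sharing the sign of the median.

    Returns ``(pd, p)`` where ``p = 2 * (1 - pd)`` is the approximate
    two-sided frequentist analogue.  ``pd`` lies in [0.5, 1].
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) < 100:
        raise ValueError("at least 100 draws are required")
    med = np.median(x)
    if med == 0:
        return 0.5, 1.0
    pd_val = float(np.mean(np.sign(x) == np.sign(med)) + 0.5 * np.mean(x == 0))
    pd_val = min(max(pd_val, 0.5), 1.0)
    return pd_val, 2.0 * (1.0 - pd_val)


def run_ensemble(
    log_prob,
    x0: np.ndarray,
    n_walkers: int,
    tune: int,
    draws: int,
    seed: int = 0,
    thin: int = 5,
) -> np.ndarray:
    """Generic ensemble-sampler driver returning flattened posterior draws.

    ``log_prob`` must accept a (walkers, ndim) batch.  Used directly by the
    toy conjugate validation tests and by the exact leave-one-out oracle.
    """
    x0 = np.atleast_2d(x0)
    ndim = x0.shape[1]
    rng = np.random.default_rng(seed)
    init = x0 + 0.1 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(
        n_walkers, ndim, log_prob, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler._random = np.random.RandomState(int(rng.integers(2**31)))
    keep = max(1, math.ceil(draws / n_walkers))
    sampler.run_mcmc(init, tune + keep * thin, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=tune, thin=thin)
    return chain.reshape(-1, ndim)[:draws]


def sample_posterior(
    model: HierarchicalObserverModel,
    chains: int = 4,
    tune: int = 1000,
    draws: int = 1000,
    target_accept: float | None = None,
    seed: int = 0,
    **kwargs,
) -> HierarchicalObserverResults:
    """Functional alias for :meth:`HierarchicalObserverModel.fit`.

    ``target_accept`` is accepted for interface compatibility with
    gradient-based samplers; the Metropolis kernel adapts its random-walk
    step internally and ignores it.
    """
    return model.fit(chains=chains, tune=tune, draws=draws, seed=seed, **kwargs)
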