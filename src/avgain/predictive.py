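"""Prior and posterior predictive checks for the hierarchical observer.

Predictive envelopes are reported as tidy tables (stimulus, gain group,
mean, sd) rather than figures: each row gives the predictive mean and
standard deviation of the pooled proportion of High-TF choices for one
stimulus/sound-level cell, from which 1-sd and 2-sd bands follow.  The
population-average curve convention is used: gains come from the
population means, the sensory noise from the population mean ``k * theta``
of its Gamma distribution, and the lapse rates are averaged across rats
(they have no group-level distribution).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .hierarchical import HierarchicalObserverModel, HierarchicalObserverResults, ModelSpec
from .observer import PROB_FLOOR, StimulusSet

__all__ = [
    "prior_predictive",
    "posterior_predictive",
    "ppc_calibration",
    "predicted_curves",
]


def _curve(s, gamma, sigma, eps_h, eps_l, s0):
    z = (gamma * s - s0) / sigma
    p = eps_h + (1.0 - eps_h - eps_l) * ndtr(z)
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def prior_predictive(
    spec: ModelSpec | None = None,
    stimset: StimulusSet | None = None,
    n_sims: int = 1000,
    n_rats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Prior predictive psychometric envelopes, one per gain group.

    Draws hyperparameters from their priors, forms the population-average
    curve for each simulation, and summarises across simulations.  Needs no
    data, so it also covers the zero-trial case.  The priors are identical
    across gain groups, so the envelopes coincide up to sampling noise.
    """
    spec = spec or ModelSpec()
    stimset = stimset or StimulusSet()
    rng = np.random.default_rng(seed)
    s = np.asarray(stimset.all_tfs)
    G = spec.n_gamma
    rows = []
    sims = np.empty((n_sims, G, len(s)))
    for i in range(n_sims):
        mu_gamma = rng.normal(0.0, 3.0, size=G)
        k = rng.exponential(3.0)
        theta = rng.exponential(3.0)
        sigma = max(k * theta, 1e-6)
        eps = rng.dirichlet((1.0, 1.0, 1.0), size=n_rats).mean(axis=0)
        eps_l, eps_h = eps[0], eps[1]
        for g in range(G):
            sims[i, g] = _curve(s, mu_gamma[g], sigma, eps_h, eps_l, stimset.s0)
    for g in range(G):
        for j, sj in enumerate(s):
            rows.append(
                {
                    "gamma_group": g + 1,
                    "visual_tf_hz": sj,
                    "mean": sims[:, g, j].mean(),
                    "sd": sims[:, g, j].std(ddof=1),
                }
            )
    return pd.DataFrame(rows)


def posterior_predictive(
    results: HierarchicalObserverResults,
    n_sims: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior predictive proportions per (stimulus, gain group) cell.

    For each retained posterior draw, simulates choice counts for every
    design cell from the per-rat parameters and pools across rats, giving a
    predictive distribution of the pooled proportion of High choices that
    includes both parameter and binomial sampling uncertainty.  The observed
    pooled proportion is attached per cell.
    """
    model = results.model
    rng = np.random.default_rng(seed)
    post = results.idata.posterior
    S = post.sizes["chain"] * post.sizes["draw"]
    take = rng.choice(S, size=min(n_sims, S), replace=False)

    gamma = post["gamma"].values.reshape(S, model.R, model.G)[take]
    sigma = post["sigma"].values.reshape(S, model.R, model.Ns)[take]
    eps_h = post["eps_h"].values.reshape(S, model.R)[take]
    eps_l = post["eps_l"].values.reshape(S, model.R)[take]
    lam = (
        post["lam"].values.reshape(S, model.R)[take]
        if "lam" in post
        else np.zeros((len(take), model.R))
    )

    g = gamma[:, model.cell_rat, model.cell_g]
    sg = sigma[:, model.cell_rat, model.cell_sg if model.Ns > 1 else 0]
    eh = eps_h[:, model.cell_rat]
    el = eps_l[:, model.cell_rat]
    lm = lam[:, model.cell_rat]
    z = (g * model.cell_s - model.stimset.s0 + (g - 1.0) * lm) / sg
    p = np.clip(eh + (1.0 - eh - el) * ndtr(z), PROB_FLOOR, 1.0 - PROB_FLOOR)
    k_sim = rng.binomial(model.cell_n.astype(int), p)  # (n_sims, n_cells)

    cell_group = pd.DataFrame(
        {
            "g": model.cell_g,
            "s": model.cell_s,
            "n": model.cell_n,
            "k_obs": model.cell_k,
        }
    )
    rows = []
    for (gi, sj), sub in cell_group.groupby(["g", "s"]):
        idx = sub.index.to_numpy()
        n_tot = sub["n"].sum()
        prop_sim = k_sim[:, idx].sum(axis=1) / n_tot
        rows.append(
            {
                "gamma_group": int(gi) + 1,
                "visual_tf_hz": float(sj),
                "n_trials": int(n_tot),
                "observed": float(sub["k_obs"].sum() / n_tot),
                "mean": float(prop_sim.mean()),
                "sd": float(prop_sim.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def ppc_calibration(ppc: pd.DataFrame, n_sd: float = 2.0) -> float:
    """Fraction of cells whose observed proportion lies inside mean +- n_sd."""
    inside = np.abs(ppc["observed"] - ppc["mean"]) <= n_sd * ppc["sd"]
    return float(inside.mean())


def predicted_curves(
    results: HierarchicalObserverResults,
    s_grid: np.ndarray | None = None,
    n_sims: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-average model curves (mean and sd) per gain group.

    Rendering data for figure-style psychometric curves: for each posterior
    draw the curve uses the group-level gain means, the Gamma-mean sensory
    noise ``k_sigma * theta_sigma`` and across-rat average lapse rates.
    """
    model = results.model
    s = np.asarray(
        s_grid if s_grid is not None else np.linspace(0.25, 4.0, 76)
    )
    rng = np.random.default_rng(seed)
    post = results.idata.posterior
    S = post.sizes["chain"] * post.sizes["draw"]
    take = rng.choice(S, size=min(n_sims, S), replace=False)
    mu_gamma = post["mu_gamma"].values.reshape(S, model.G)[take]
    sigma = (post["k_sigma"].values * post["theta_sigma"].values).reshape(S)[take]
    eps_h = post["eps_h"].values.reshape(S, model.R)[take].mean(axis=1)
    eps_l = post["eps_l"].values.reshape(S, model.R)[take].mean(axis=1)
    rows = []
    for g in range(model.G):
        curves = _curve(
            s[None, :], mu_gamma[:, g, None], np.maximum(sigma, 1e-6)[:, None],
            eps_h[:, None], eps_l[:, None], model.stimset.s0,
        )
        for j, sj in enumerate(s):
            rows.append(
                {
                    "gamma_group": g + 1,
                    "visual_tf_hz": float(sj),
                    "mean": float(curves[:, j].mean()),
                    "sd": float(curves[:, j].std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)
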