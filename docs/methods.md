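# Methods

`avgain` implements a complete, simulation-tested analysis pipeline for an
audiovisual psychophysics experiment in which rats classify the temporal
frequency (TF) of a drifting grating as "Low" or "High" while task-irrelevant
sounds play. The scientific question is whether, and how strongly, the
average intensity of the concurrent sound compresses the animal's internal
representation of visual temporal frequency. The pipeline covers five
stages: acoustic stimulus calibration, the ideal-observer choice model,
synthetic cohort generation, hierarchical Bayesian inference, and predictive
model comparison, plus the conventional frequentist summaries.

## Acoustic stimuli and calibrated intensity

Sound stimuli are dimensionless control signals in [-1, 1] at 44.1 kHz:

- **Fixed-amplitude noise** — Gaussian white noise normalised into [-1, 1]
  with effective standard deviation `sigma_eff = 0.283`. We realise the
  normalisation by scaling a unit-variance sequence to `sigma_eff` and
  clipping the negligible mass beyond ±1 (≈3.5 sigma), which reproduces the
  calibrated effective std by construction.
- **Amplitude-modulated (AM) noise** — uniform[-1, 1] white noise multiplied
  by the raised-cosine envelope `m(t) = (1 - cos(2 pi nu t))/2`, with nu one
  of the nine task TFs (0.25–4 Hz). One carrier sequence is shared by all
  trials of a condition, as in the experiment.
- **Silence** — the ambient noise floor of the chamber, `La = 32` dB.

A single calibration factor `f = 0.39` Pa per control-signal unit maps
signals to pressure. Levels always include the ambient pressure
`p_a = p0 * 10^(La/20)` (reference `p0 = 20` µPa):

    L = 10 log10((p_rms^2 + p_a^2) / p0^2)

so no computed level can fall below `La`; the fixed-amplitude stimulus
calibrates to `L(f * sigma_eff) = 74.8` dB. For AM sounds the closed-form
intensity profile follows from the carrier RMS `sqrt(1/3)`:

    L_AM(t) = 10 log10(((f * a_bar * m(t)) / p0)^2 + (p_a / p0)^2)

**Validation of the profile.** The closed form describes the *expected*
level inside a sliding RMS window of width `tau = 5` ms. A single window
holds ~220 carrier samples, so one measured profile fluctuates around the
closed form with ≈0.26 dB standard deviation; the numeric validation
therefore averages the sliding-RMS profile over 24 independent carriers,
which resolves differences well below the 0.5 dB tolerance. Within a few
`tau` of the envelope minima the raised cosine varies too quickly for the
windowed RMS to track it (a real curvature bias, >1 dB at 4 Hz); those
points violate the scale-separation assumption under which the closed form
is derived and are excluded from the comparison.

**Perceived intensity.** The intensity a rat experiences on a trial is the
time-average of the dB profile over the reaction-time window
`[0, RT - MoRsT]`, with the motor response time fixed at `MoRsT = 0.3` s
(the duration of a ballistic head movement to a response port). Averaging
in dB is the default; averaging mean-square pressure first is available as
an option and yields systematically higher values because loud segments
dominate. The eleven conditions collapse onto five intensity *levels*:
silence < AM 0.25 Hz < AM 0.82 Hz < AM 1.32–4 Hz < fixed. The grouping rule
is fixed by condition identity; the measured means are only used to verify
that the grouping is monotone in level. That monotonicity holds at
task-typical reaction times (≈0.5 s, where the means fall near 32 / 50 /
67 / 70 / 75 dB); for much longer averaging windows the 0.82 Hz condition
approaches and eventually overtakes the fast cluster, because dB-domain
averaging of a slowly ramping profile keeps rising while the fast cluster's
full-cycle average is fixed.

## Ideal observer with sound-dependent gain

On each trial the observer forms a scalar Gaussian measurement
`x ~ N(a + b*s, rho^2)` of the grating TF `s` and reports High when `x`
exceeds the boundary learned in training. For the linear encoding the
Bayes boundary is exactly `x* = a + b*s0` with `s0 = 2.12` Hz (we verify
this against a numeric root of the 9-component class-mixture posterior; the
identity is exact for a stimulus set symmetric around `s0` in linear
stimulus units — the task grid is symmetric on a log scale, so there it
holds only to ≈0.02 Hz). A concurrent sound of intensity level `n` scales
the mean encoding by a gain `gamma_n` while the boundary stays fixed,
giving, with lapse rates:

    p(H | s, n) = eps_H + (1 - eps_H - eps_L) *
                  Phi[(gamma_n s - s0 + (gamma_n - 1) lambda) / sigma]

with `sigma = rho / b`, `lambda = a / b` (zero in the core model, optional
as a fitted parameter). Note that `p(H)` is *increasing* in `gamma` for
`s > 0`: quiet conditions, which have larger gains (silence ≈ 1.36 vs fixed
≈ 0.99 under the fitted linear gain-intensity relation), shift choices
toward High, most prominently for mid-to-high TFs. Probabilities are
clipped to `[1e-12, 1 - 1e-12]` before entering any likelihood.

A brute-force generative observer (explicit measurement draws plus the
mixture-posterior decision rule) is kept solely as an oracle: it must agree
with the closed form within binomial Monte-Carlo error for any `(a, b,
rho, gamma)`.

## Synthetic cohorts

Because no trial-level data ships with the package, every downstream stage
is exercised on synthetic cohorts that reproduce the task structure:

- four trial categories (visual + fixed sound, visual + AM sound, visual
  only, auditory only) with weights proportional to the design-matrix cell
  counts (9 : 81 : 9 : 9);
- uniform stimulus sampling within category, subject to the task rule that
  at most three consecutive trials may show the same visual class
  (enforced by redrawing from the opposite class; auditory-only trials
  carry no grating and reset the run);
- choices drawn from the psychometric model with per-rat parameters sampled
  from the population distributions; auditory-only choices are fair coins
  (rats show no sensitivity to auditory TF);
- response times from a lognormal with median 0.7 s and geometric sd 1.4,
  truncated to (0.3, 2.0] s — the task's response window. The RT model is
  a plausible rodent choice-latency distribution whose only role is to
  exercise the perceived-intensity window; nothing downstream is sensitive
  to its exact shape.

Population defaults follow the fitted linear gain–intensity relation
(slope −8.6·10⁻³ per dB, intercept 1.636) evaluated at the five level
intensities, between-rat gain sd 0.1, and `sigma ~ Gamma(k=10,
theta=0.06)` (mean 0.6 Hz). The lapse simplex defaults to Dirichlet(1,1,1),
mirroring the inference prior; note this routinely produces rats with near-
zero task engagement, whose gains are unidentifiable — useful for testing
robustness, not representative of trained animals. The *recovery and
model-selection studies* therefore use Dirichlet(1,1,8) lapses (mean lapse
≈0.1 per side), consistent with animals that had to sustain ≥70% accuracy
to enter the test phase, and gain means spaced 0.15 apart
(1.50, 1.35, 1.20, 1.05, 0.90) so that a desk-scale cohort can resolve the
ordering; the paper-derived defaults put adjacent levels only ~0.03 apart,
which would require far larger cohorts.

What the generator deliberately omits: learning and motivation dynamics,
session effects, reward/timeout bookkeeping, and any RT–difficulty
dependence. Passing tests therefore demonstrate the *methods* are correct
and well calibrated on data matching the model's assumptions; they cannot
certify behaviour on real animals.

## Hierarchical Bayesian inference

Per rat `r`: `(eps_L, eps_H, 1-eps_L-eps_H) ~ Dirichlet(1,1,1)`,
`sigma_r ~ Gamma(k_sigma, theta_sigma)` (shape/scale), and
`gamma_nr ~ N(mu_gamma_n, sd_gamma_n^2)` — untruncated, as specified.
Hyperpriors: `mu_gamma_n ~ N(0, 9)`, and Exponential(scale 3) for
`sd_gamma_n`, `k_sigma`, `theta_sigma` (and `sd_lambda` in the lambda
variant; `mu_lambda ~ N(0, 9)`). The likelihood is the Bernoulli product
of the psychometric probabilities; internally trials collapse onto
(rat, stimulus, gain-group, noise-group) cells with binomial counts, which
makes a likelihood evaluation O(cells) rather than O(trials).

Model variants: 1 or 5 sensitivities; 1, 5 (per level) or 11 (per
condition) gains; an optional hierarchical per-rat `lambda`; and a variant
whose level-wise gain means lie on a line in average sound level (dB), with
`N(0, 9)` priors on slope and intercept. The sigma hyperparameters are
shared across levels in the 5-sigma variants. Auditory-only trials and
trials with missing response times are excluded from the likelihood with a
recorded count. Boundary-stimulus (2.12 Hz) trials are included by default
and can be excluded.

**Sampling.** Parameters are transformed to an unconstrained space (log for
positives, stick-breaking for the lapse simplex; gains and lambda are kept
centred). The sampler is a bank of fully independent Metropolis chains,
warmed up adaptively:

1. The posterior mode is located in an auxiliary non-centred
   parameterisation (where the hierarchy's `sd -> 0` density spike is
   absent, so the mode is interior), and a Laplace covariance is propagated
   back through the transform's Jacobian.
2. Four adaptation windows re-estimate the proposal mean and covariance
   from the pooled cross-chain states and tune the random-walk step toward
   25% acceptance. All adaptation states are discarded.
3. With the kernel frozen, the bank alternates two moves: an independence
   proposal (multivariate t, 4 degrees of freedom, at the adapted mean —
   large decorrelating jumps) and a covariance-preconditioned random walk
   (local exploration wherever the Gaussian summary is imperfect).

Draws are thinned snapshots of the bank; the requested `chains` are
disjoint groups of the independent chains, so split-R-hat across them is a
genuine convergence diagnostic. Diagnostics (R-hat, bulk/tail ESS, MCSE,
3–97% HDI) come from ArviZ; a fit is flagged non-converged (not fatal) when
any hyperparameter R-hat exceeds 1.01. Determinism: all randomness derives
from a single seed; identical seeds give identical draws.

Default profiles: 2 chains × 500 draws (tune 800) for test-scale work,
4 × 1000 (tune 1000) for replication runs. A typical 8-rat × 1200-trial fit
takes a few seconds on one CPU; quoted study sizes below reflect that
budget. A differential-evolution ensemble sampler is retained as
`fit(method="ensemble")`.

**Predictive checks.** Prior predictive: 1000 hyperparameter draws from the
priors, population-average curves per gain group (gains = group means,
sigma = `k*theta`, lapses averaged over simulated rats); the priors are
symmetric across groups, so the envelopes coincide up to sampling noise.
Posterior predictive: for each retained draw, binomial choice counts are
simulated for every design cell from the per-rat parameters and pooled; a
fit is well calibrated when ≥95% of (stimulus, level) cells fall inside the
2-sd envelope. Curve-rendering data (mean ± sd psychometric curves per
level) are emitted as tables, not figures.

## Model comparison

Out-of-sample predictive quality is the LOO expected log pointwise
predictive density,

    ELPD_LOO = sum_i log E_post(-i)[p(d_i | theta)],

estimated by Pareto-smoothed importance sampling over the full-data
posterior (smoothing via ArviZ's `psislw`; trials with Pareto shape
k > 0.7 are flagged). The standard error is `sqrt(N) * sd` of the pointwise
contributions, and model differences use the paired pointwise SE. A
sorted-table digest of the trial set guards comparisons against silently
mismatched data. The approximation is anchored by an exact oracle that
refits the model once per left-out trial (feasible only for ≤~60 trials);
for a single trial the oracle returns the prior-predictive log density.
`probability_of_direction` reports the fraction of posterior mass sharing
the sign of the median, with the approximate two-sided `p ≈ 2(1-pd)`.

## Frequentist reporting

Per-rat proportions of High choices are aggregated by audiovisual
congruency (diagonal = congruent, anti-diagonal = anti-congruent, the rest
incongruent; the centre cell lies on both diagonals, is tabulated as
congruent, and is shared into the anti-congruent pool when a balanced
9-TF design is needed) or by intensity level. Proportions are
arcsine-square-root transformed; Shapiro–Wilk normality per cell and Levene
homoscedasticity across conditions are checked; the two-way
repeated-measures ANOVA (visual TF × condition) is computed with pingouin,
reporting uncorrected p-values with Greenhouse–Geisser-corrected values
alongside where available; Tukey HSD pairwise contrasts between conditions
are reported on both the raw and transformed scales (statsmodels).

## Numerical choices and limitations

- Probability floor 1e-12 before logs; positivity transforms clipped at
  exp(±300); Laplace covariance eigenvalues floored at 1e-8 of the largest.
- The generator truncates gains at zero (an observer needs positive gain);
  the inference prior is left untruncated as specified. With the default
  Dirichlet(1,1,1) lapses the mismatch is immaterial because disengaged
  rats dominate the tails anyway.
- Empirical probit regression per rat initialises the mode search; fits are
  insensitive to this start beyond run time.
- Study sizes used by the shipped checks: recovery 4 replicates of 8 rats ×
  1200 trials; model selection 8 rats × 1000; exact-LOO validation 10 sets
  of 30 trials (3 rats × 10); schedule checks 100 × 10⁴ trials.
- Known limitations: the independence-Metropolis component can linger on
  isolated importance-weight outliers (visible as R-hat ≈ 1.02 on skewed
  scale hyperparameters at small draw counts); the exact-LOO oracle is
  Monte-Carlo noisy at very small posterior sample sizes; and the ANOVA
  path requires a balanced design by construction and refuses otherwise.
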