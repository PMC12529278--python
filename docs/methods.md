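# Methods

This note documents the models, the synthetic data they are validated on,
and the numerical choices the package makes where the design was open.

## The reporting model

**Model.** Respondent i reports a lifetime event count Y_i over exposure
t_i > 0 years. The true count Y*_i is zero-inflated Poisson: with
probability φ_i the count is structurally zero; otherwise it is
Poisson(λ_i t_i), with λ_i = exp(β·X_i) and φ_i = logistic(δ·Z_i). Each true
event is reported independently with probability π_i = logistic(γ·W_i)
(binomial thinning). Thinning a ZIP yields a ZIP with thinned mean, so the
observed count follows ZIP(π_i λ_i t_i, φ_i) exactly. The likelihood is
maximized in this closed form; the explicit ZIP × Binomial convolution is
retained purely as a test oracle, and the two are asserted equal to 1e-10 on
a grid in the suite.

**Exposure.** Exposure runs from the earlier of menarche and first
intercourse to interview. The generator draws menarche from ages 11–16,
first intercourse from 15–25 and interview from 25–49 (discrete stand-in
distributions chosen for realistic location and spread); exposure is floored
at half a year. A `fixed_exposure` option supports moment-identity checks.

**Estimation.** Unweighted maximum likelihood via L-BFGS-B with numeric
gradients from five starts: a null start (all coefficients zero except the
count intercept at log(mean y / mean t)) plus four seeded N(0, 0.5)
perturbations, followed by a tighter polishing pass from the winner. The
coefficient covariance is the pseudo-inverse of the numerically
differentiated observed Hessian, with small negative eigenvalues (numerical
noise near saturated reporting cells) clipped to keep it positive
semidefinite. Non-convergence is recorded on the fit object, never raised.
Survey weights are deliberately not used in the likelihood; they are honored
only in descriptive tabulations.

**Identification, honestly.** The observed data follow ZIP(πλt, φ), so π is
never identified separately from λ by the count distribution itself — only
by the functional-form restriction that log μ must decompose as
β·X + log logistic(γ·W). With a single reporting covariate that restriction
is vacuous (any cell-level factor can be absorbed into the count equation),
and when true reporting is essentially complete the log-logistic curvature
vanishes, leaving a perfectly flat ridge along π·λ = const. Concretely:

- `BTZIPSpec.validate` emits an `IdentificationWarning` when the count and
  reporting equations share the same covariate set.
- The acceptance suite asserts the ridge is numerically flat (< 1e-6 change
  in log-likelihood) for an intercept-only specification.
- The average-rate estimate is reliable only when several reporting
  covariates with effects away from saturation overlap; the robustness sweep
  (`misreport.selection`) exists precisely to expose how much the estimate
  moves across specifications, and dropping the key excluded covariate is
  demonstrated to move it most.

**Reporting-rate summaries.** The headline rate is the arithmetic mean of
predicted π_i over rows (per subgroup when requested), in percent. Its
standard error is by the delta method: the gradient of the mean of
logistic(γ·W_i) with respect to the full coefficient vector, sandwiched with
the coefficient covariance. Rates are displayed to one decimal, so values
above 99.95 print as 100.0. The delta-method SE is validated against the SD
of the mean rate over 500 coefficient vectors drawn from the asymptotic
normal — on a well-conditioned scenario; near saturation the asymptotic
normal is a poor description and the two legitimately disagree.

## Prevalence correction

corrected_k = (reported_k / rate_k) / Σ_j (reported_j / rate_j) × 100, with
rates accepted in percent and outcomes missing from the rate vector treated
as fully reported. Full precision is kept internally; one-decimal rounding
is display-only. The operation is exactly invertible (multiply by rates,
renormalize), invariant under a common rate, and monotone: lowering one
outcome's rate strictly raises its corrected share. No estimation
uncertainty is propagated into corrected shares; that is a possible
extension, not implemented.

## Model selection

Candidates are user-declared labelled `BTZIPSpec`s. All candidates are fit
on one shared complete-case sample built from the union of their covariates,
so AIC/BIC are computed on identical observations and are comparable.
Invalid candidates (missing columns) and failed fits are recorded and do not
stop the family. Ranking ties break lexicographically by label. AIC/BIC are
recomputable from the stored log-likelihood and parameter count to 1e-10 by
construction.

## The outcome-risk model

**Model.** Pregnancy j of woman i ends in outcome k ∈ {miscarriage,
abortion, live birth}; with the live-birth linear predictor fixed at zero,
η_ijk = β_0k + β_k·X_ij + u_ik and P(Y_ij = k) ∝ exp(η_ijk). Each
non-reference outcome has its own random-intercept SD σ_uk and independent
u's — the more general rendering of a woman-level effect; a shared SD is its
special case. Priors: Normal(0, 5²) on fixed effects, half-Student-t(3, 2.5)
on σ_u. Categorical covariates are dummy-coded against a fixed canonical
category order.

**Sampler.** Adaptive Metropolis-within-Gibbs, implemented in numpy:

- scalar random-walk updates per fixed-effect coefficient, with the linear
  predictor updated incrementally (one O(n) pass per coefficient);
- a vectorized per-woman random-walk update for the u's (independent
  accept/reject across women given the rest);
- a random-walk update on log σ_u; and
- a joint rescaling move (u_k, σ_uk) → (c·u_k, c·σ_uk) per outcome. The
  N(0, σ²) prior term on u is invariant under this move, so it travels along
  the funnel direction that the conditional updates cannot; without it the
  σ_u chain is effectively stuck (split-R̂ above 2 in early experiments,
  ~1.02 with it).

Proposal scales adapt toward 44% acceptance during warmup only
(Robbins-Monro, weight 1/√iter), so the post-warmup chain is a valid
time-homogeneous Markov chain. Chains (default 4 × 6000 iterations, warmup
half) run sequentially from a common start with intercepts at empirical
log-odds; per-chain RNGs come from `SeedSequence(seed).spawn`, making runs
bit-reproducible. Split-R̂ and bulk ESS (via arviz) are attached to every
reported parameter; R̂ > 1.05 or ESS < 100 sets a warning flag on the fit —
returned, never raised.

**No-random-effect variant and MAP.** `fit_no_re` runs the same sampler with
u ≡ 0 and additionally stores a maximum-a-posteriori estimate from direct
L-BFGS-B optimization of the log posterior, which the tests compare against
an independently configured optimizer (1e-4) and against posterior means on
well-identified data (0.1).

**Predicted probabilities.** Marginal standardization: for each posterior
draw, the profile variables are fixed on every observed covariate row,
probabilities are averaged over rows and over ≥200 Monte-Carlo draws of u
from that draw's σ_u, and the 95% interval is the 2.5/97.5 percentile across
posterior draws. At most 400 posterior draws are used (seeded subsample) to
bound cost.

## The synthetic generator

The generator emulates the structure of a national retrospective
reproductive-health survey: respondent-level thinned-ZIP counts with
covariate-dependent rate, inflation and reporting; and per-woman pregnancy
sequences whose outcomes follow the random-intercept multinomial logit, with
parity and prior-miscarriage categories recomputed from the simulated
history before each pregnancy. Covariates are drawn independently from
declared category marginals (a correlation structure is not modelled); the
number of pregnancies per woman is zero-inflated Poisson. All randomness
flows from one seeded generator per call; respondent and pregnancy tables
use distinct child streams of the config seed.

`fecond_like_preset` is the documented default condition: covariate
marginals loosely matching the survey's descriptive table, an average true
reporting probability of ~92% with near-complete reporting among
tertiary-educated women, a ~14% miscarriage share of pregnancy outcomes and
~10% abortions, and exclusion restrictions between the count covariates
(parity, smoking, BMI, infertility treatment) and the reporting covariates
(marital status, health, income). Two calibration choices matter and are
deliberate:

- The reporting coefficients place one income cell near π ≈ 0.45 while most
  of the population sits near the ceiling. This spread supplies the
  log-logistic curvature the MLE needs; with reporting probabilities
  compressed into [0.8, 1.0] the likelihood is too flat for stable recovery
  at any realistic sample size.
- The mean reported count is ~0.55 events per woman (count intercept −4.0).
  Recovery of the average reporting rate to ±3 percentage points at n = 8000
  was verified across several generator seeds at this event rate before it
  was frozen; at lower rates the estimate wanders along the ridge.

`frailty_scenario` switches on a shared woman-level Normal(0, 1) term that
multiplies the pregnancy rate and shifts the miscarriage predictor while the
true prior-miscarriage coefficient is zero, with a longer mean history (3
pregnancies) for within-woman replication and a lowered baseline so marginal
shares stay plausible. On this data a no-random-effect fit attributes a
clearly positive effect to prior miscarriages and the random-intercept fit
attenuates it — the qualitative contrast, not any real-data magnitude, is
what the tests assert.

**What passing tests do not show.** The generator draws covariates
independently, has no item nonresponse, no interviewer or mode effects, no
misclassification between outcome types, and its exposure-age distributions
are stand-ins. Passing recovery tests therefore demonstrates the estimators
are correct under the model's own assumptions, not that those assumptions
hold in any real survey.

## Problem sizes and numerical defaults

Validation runs use n = 8000 respondents for reporting-model recovery and
selection, 500–3300 pregnancies for the risk model, and reduced MCMC (2–4
chains × 2000–4000 iterations) — sizes at which the checked properties are
comfortably resolved. Optimizer tolerances: L-BFGS-B ftol 1e-11 / gtol 1e-7
for the multistart phase, 1e-15 / 1e-9 for polishing and MAP. Degenerate
inputs fail loudly and early: nonpositive exposure, unseen categories,
single-outcome pregnancy tables, nonfinite coefficients and malformed CSV
rows are all rejected with the offending item named, and every exclusion is
counted so input rows always reconcile as used + excluded.

## Known limitations

- The BT-ZIP average reporting rate is a fragile estimand by construction;
  under weak identification the MLE can sit several percentage points from
  the truth with deceptively small within-specification standard errors.
  Specification sweeps, not single fits, are the honest summary.
- The argmax of a near-flat likelihood is reproducible only to optimizer
  precision: refitting permuted rows reproduces the likelihood value and the
  headline rate closely, but not individual coefficients to machine
  precision.
- The Metropolis-within-Gibbs sampler is far less efficient per iteration
  than gradient-based samplers; σ_u parameters have the lowest ESS and can
  warn at short chain lengths even when point summaries are stable.
- Corrected prevalences carry no uncertainty from the estimated reporting
  rates.
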