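# misreport

Misreporting-adjusted analysis of retrospective pregnancy histories.

Population surveys that collect full pregnancy histories are the main source
of representative evidence on miscarriage and induced abortion, but both
outcomes are underreported: some respondents omit events entirely, others
report a positive but too-small lifetime count. `misreport` implements, as a
single tested pipeline, the three pieces an analyst needs to work with such
data:

1. **A binomially-thinned zero-inflated Poisson (BT-ZIP) reporting model.**
   The true lifetime event count follows a zero-inflated Poisson,

   ```
   P(Y* = 0)      = φ + (1 − φ) e^{−λt}
   P(Y* = y), y>0 = (1 − φ) (λt)^y e^{−λt} / y!
   ```

   with event rate λ = exp(β·X) per year of exposure t (years since the
   earlier of menarche and first intercourse) and zero-inflation probability
   φ = logistic(δ·Z). Each true event is independently reported with
   probability π = logistic(γ·W) (binomial thinning, Y = π ∘ Y*), so the
   *observed* count is exactly ZIP(πλt, φ). All coefficients are estimated
   jointly by maximum likelihood; the average of the predicted π over
   respondents, in percent, is the headline *reporting rate*, with
   delta-method standard errors. Separating π from λ rests on exclusion
   restrictions between X and W, and the package warns when a specification
   offers none.

2. **Prevalence correction.** Given reported outcome shares s_k and
   reporting rates r_k, the corrected share is
   (s_k/r_k) / Σ_j (s_j/r_j) × 100 — outcomes absent from the rate vector
   are assumed fully reported.

3. **A multilevel multinomial risk model.** Pregnancy outcome (miscarriage /
   abortion / live birth as reference) follows a multinomial logit
   η_ijk = β_0k + β_k·X_ij + u_ik with woman-level random intercepts
   u_ik ~ N(0, σ_uk²), fit by an adaptive Metropolis-within-Gibbs sampler
   with weakly informative priors. Contrasting fits with and without the
   random effects shows whether an apparent effect of reproductive history
   (e.g. prior miscarriages) survives once time-invariant unobserved
   heterogeneity is modelled.

Because the survey microdata such analyses use are typically restricted, the
package ships a first-class synthetic generator (`misreport.synthetic`) that
reproduces the exact statistical structure the models assume — thinned ZIP
counts, exposure from menarche/first-intercourse ages, per-woman pregnancy
sequences with running parity and miscarriage bookkeeping, and an optional
shared frailty linking history length to miscarriage risk — so every stage
is testable end to end.

## Worked example

```python
from misreport import btzip, correction, synthetic

cfg = synthetic.fecond_like_preset(n_women=8000, seed=42)
respondents = synthetic.simulate_respondents(cfg)

spec = btzip.BTZIPSpec(
    count_covariates=["education", "age_group_survey", "parity_survey",
                      "infertility_treatment", "ever_smoked", "bmi_category"],
    zero_covariates=["education"],
    report_covariates=["education", "marital_status", "health", "income"],
)
fit = btzip.fit(respondents, spec, seed=0)
table = btzip.average_reporting_rate(fit, respondents, by="education")
print(table.formatted().to_string(index=False))
```

```
                subgroup  rate_pct  se_pct    n
                 Average      92.3    0.56 8000
education=below_tertiary      89.3    0.78 5769
      education=tertiary     100.0    0.00 2231
```

The generator's true average reporting probability for this draw is 91.2%,
so the model recovers the reporting rate to about one percentage point and
reproduces the education gradient it was given (near-complete reporting
among tertiary-educated women, printed as 100.0 after one-decimal rounding). Correcting a reported outcome distribution
by such rates:

```python
from misreport.correction import OutcomeDistribution, RateVector
reported = OutcomeDistribution(
    labels=["miscarriage", "abortion", "live_birth", "other"],
    shares=[13.9, 10.3, 72.8, 3.0])
corrected = correction.correct_distribution(
    reported, RateVector({"miscarriage": 92, "abortion": 55}))
print(corrected.rounded())
```

```
{'miscarriage': 13.8, 'abortion': 17.1, 'live_birth': 66.4, 'other': 2.7}
```

A miscarriage reporting rate this high barely moves the miscarriage share
(13.9 → 13.8%), while the much lower abortion reporting rate shifts
substantial mass toward abortions — the qualitative point the correction
exists to make.

## Command line

`misreport` installs a CLI with subcommands `simulate`, `fit-reporting`,
`select-model`, `correct`, `fit-risk` and `run-all`; see `misreport --help`.
`run-all` executes the full pipeline from a YAML config (or the built-in
preset) and writes all tables, fit objects and a JSON run report with
complete exclusion accounting into `--out-dir`.

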