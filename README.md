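# somamat

Somatic maturity estimation and maturity-biased selection modelling for
longitudinal athlete cohorts.

In physically demanding youth sports, biologically more mature adolescents
are bigger and stronger than their age-matched peers, and selectors tend to
favour them — while late maturers who survive the junior system may convert
to senior success at elevated rates (the "underdog" pattern). `somamat`
implements the full analysis pipeline needed to study this with school-type
longitudinal height records:

1. **Percent of adult height (%AH)** — baseline stature divided by final
   (adult) stature × 100, a non-invasive somatic maturity indicator. Adult
   height comes from the final (sixth-semester) measurement, or from an
   externally recovered value when follow-up is missing. Entry-error
   cleaning: %AH in (100, 102] is clamped to 100; %AH > 102 is excluded.
2. **z-scores and biological age** — %AH is compared with an age-matched
   growth reference (mean and SD of %AH on an age grid). The *biological
   age* is the age at which the reference mean %AH equals the player's %AH
   (inverse lookup, to one decimal); the *age offset* is biological minus
   chronological age (positive = early maturing).
3. **Maturity-timing categories** — early / on-time / late by z-score
   (on-time: −0.5 ≤ z ≤ 0.5) and by age offset (±0.5 years).
4. **Selection models** — binomial generalised linear mixed models with a
   logit link and a random intercept for high-school region:

   * junior: `team16 ~ z(%AH) + year + (1 | region)`
   * adult:  `nhl ~ z(%AH) + year + team16 + team18 + team20 + (1 | region)`

   fitted by maximum likelihood under the Laplace approximation, with Wald
   95% CIs, AIC, and likelihood-ratio tests against univariable nulls.
5. **Synthetic cohort generator** — growth trajectories driven by adult
   height and a latent maturity-timing offset applied to the reference
   curve, plus measurement noise, data-entry errors, loss to follow-up and
   maturity-dependent multi-stage selection, with a per-player truth table.
   Because real national growth references and ice-hockey school records are
   not redistributable, the package ships a clearly labelled
   `synthetic-default` reference table and is fully testable end-to-end
   without any external data.

## Worked example

```python
import somamat as sm

ref = sm.synthetic_default_reference()          # labelled synthetic reference
cfg = sm.SyntheticCohortConfig(n_players=2000, seed=7,
                               measurement_sd=0.0, p_entry_error=0.0,
                               p_lost_followup=1.0,
                               recovered_height_policy="all",
                               p_birthdate_missing=0.0)
records, truth = sm.simulate_cohort(cfg, ref)

from somamat.pipeline import estimate_cohort
estimates = estimate_cohort(records, ref)
frame = sm.cohort_frame(records, estimates)

fit = sm.fit_selection_model(frame, sm.team16_spec())
print(fit.coefficients.loc["z_pah"])
```

prints (cohort simulated with a true team-16 log-odds effect of +0.21 per
z of %AH):

```
estimate    0.195129
ci_low      0.084076
ci_high     0.306183
p_value     0.000574
Name: z_pah, dtype: float64
```

i.e. the junior-selection model recovers a significantly positive maturity
effect of 0.195 (95% CI 0.084–0.306) log-odds per z-unit of %AH, consistent
with the generating value within its confidence interval. The same fit on
this cohort agrees with R's `lme4::glmer` (Laplace) to four decimals.

The command line mirrors the library:

```bash
somamat run --seed 1 --out results_run          # simulate → estimate → fit → report
somamat simulate --seed 1 --out cohort          # synthetic cohort + truth table
somamat estimate --measurements cohort/measurements.csv \
                 --roster cohort/roster.csv --out est
```

`somamat run` writes the maturity-estimate table, the attrition summary,
the junior-team × NHL success crosstab, category distributions, model
coefficient tables with AIC/LRT summaries, per-player predicted
probabilities, and a manifest with the seed, a config hash and the
reference table's provenance label. Identical config and seed give
byte-identical outputs.

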