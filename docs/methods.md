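# Methods

## The maturity-estimation procedure

For each player the pipeline computes, in order:

1. **Raw %AH**: `100 × h_baseline / h_adult`, unrounded. The baseline is the
   earliest-semester height; adult height is the sixth-semester measurement
   when present, otherwise an externally recovered adult height, otherwise
   the player is *lost to follow-up* and excluded from maturity analyses.
2. **Cleaning**: raw %AH ≤ 100 passes through; values in (100, 102] are set
   to 100 (apparent shrinkage from baseline to adulthood is attributed to
   baseline measurement error); values > 102 are excluded as unreliable.
   The rule is idempotent and every outcome carries a QC flag
   (`ok`, `clamped_100`, `excluded_gt102`, `extrapolated_low`).
3. **z-score**: `(pah − mean_ref(age)) / sd_ref(age)`, with mean and SD
   linearly interpolated on the reference age grid.
4. **Biological age**: inverse linear interpolation of the reference mean
   curve at the player's %AH, rounded half-up to one decimal. %AH = 100 maps
   to the terminal age (the grid's last age, where the mean reaches exactly
   100); %AH below the first grid mean maps to the first grid age and is
   flagged `extrapolated_low`; flat mean segments resolve to the youngest
   age attaining the value (deterministic, biologically conservative).
5. **Age offset**: biological age minus chronological age, computed from the
   *rounded* (0.1 y) ages so reported offsets are reproducible from reported
   ages. Chronological age comes from the birth date when available
   (decimal years, rounded to 0.1); players without birth dates receive a
   configurable cohort default (16.2 y, the typical age in the first autumn
   semester of the year a player turns 16), flagged `cohort_default`.
6. **Categories**: early / on-time / late by z (−0.5 ≤ z ≤ 0.5 on-time) and
   by offset (±0.5 y). Boundary values classify as on-time by default; an
   open-interval variant is available via `ClassificationConfig`. Under a
   standard-normal z population the three groups have probabilities
   (0.309, 0.383, 0.309) — roughly equal thirds.

## The growth reference

A `GrowthReferenceTable` is any age grid with non-decreasing mean %AH,
positive SDs, and mean exactly 100 at the last age. Real national reference
values are not redistributable, so the default is a synthetic table
(provenance label `synthetic-default`, echoed in every manifest) built from
a logistic maturation curve

```
mean(age) ∝ 0.70 + 0.30 · logistic((age − 13.2) / 0.9),   age ∈ [12, 18]
```

rescaled to reach 100% at 18 y. This gives ≈ 85% at 13.2 y, ≈ 97% at 15 y,
≈ 99% at 16.2 y — a plausible shape around male peak height velocity. The SD
is the local slope of the mean curve times a reference timing SD of 0.85 y
(floored at 0.3%): if between-boy %AH variation at a given age is mostly
maturity-timing variation, one year of timing shift moves %AH by one slope
unit. Any user table with columns `age,mean_pah,sd_pah` replaces it.

Numerical choices: linear interpolation in age for mean and SD (minimal
assumption on a dense grid); half-up rounding of biological age to 0.1 y;
inverse lookup verified in tests against a brute-force 0.001-step scan.

## The synthetic cohort

The latent maturity driver is a single timing offset Δ per player,
Δ ~ N(0, 1.0 y²): height at age *a* is
`adult_height × mean_ref(a + Δ)/100` plus N(0, 0.5²) cm measurement noise,
so **positive Δ = early maturing** and a correct estimation chain recovers
the age offset = +Δ. Six semesters 0.5 y apart start at baseline age
~ N(16.2, 0.3²); adult height ~ N(181, 6.5²) cm; weight follows a per-player
BMI ~ N(22.5, 1.5²). Measurement dates and birth dates are real calendar
dates consistent with the drawn baseline age.

Realism features, each individually switchable:

* **entry errors** (default 5%): the baseline height is inflated so raw %AH
  lands in (100.2, 103], exercising the clamp/exclude rules;
* **loss to follow-up** (default 50%): the sixth-semester row is dropped;
  recovered adult heights are then emitted for NHL players (policy `nhl`,
  mirroring how adult heights can be recovered from public rosters), for
  everyone (`all`), or for no one (`none`);
* **missing birth dates** (default: all non-elite players), so the cohort
  default chronological age is exercised;
* **multi-stage selection**: region random intercepts u ~ N(0, 0.3²) per
  stage, then `team16 ~ Bernoulli(logit⁻¹(−2.22 + 0.21·z + u))`, analogous
  team-18/20 stages (intercept −2.31; maturity effects +0.10 and 0), and
  `nhl ~ Bernoulli(logit⁻¹(−3.9 − 0.50·z + 1.2·team18 + 2.5·team20 + u))`.
  The maturity effects ±0.21/−0.50 per z of %AH are the published junior and
  adult effect sizes; the intercepts reproduce the published marginal shares
  (9.8% team 16, ≈9% teams 18/20, ≈4.3% NHL). The timing SD of 1.0 y is a
  plausibility choice (the published baseline biological-age SD of 0.9 y
  back-solves to ≈0.85 y of timing SD after removing baseline-age spread).

What the simulator does **not** emulate: correlated progression through
junior teams (stages are conditionally independent given maturity and
region), tempo variation beyond a pure timing shift, secular height trends
across collection years, position effects, and non-Gaussian measurement
error. Passing tests therefore demonstrate correctness of the estimation
and inference machinery under the stated generative model, not fidelity of
any particular real cohort.

## Selection models

Both models are binomial GLMMs with logit link and a single random
intercept (high-school region). The maturity term enters as the z-score of
%AH by default (matching the scale of the published effect sizes); a
raw-%AH option exists. Year of collection enters as a numeric covariate.

The marginal likelihood integrates the region intercepts out with the
**Laplace approximation**: for each group the conditional mode is found by
a damped 1-D Newton iteration (vectorised across groups), and the
log-marginal adds the usual −½ log|curvature| correction. The outer
optimisation is L-BFGS-B over (β, log σ) with non-intercept columns
centered for conditioning; σ is bounded in [10⁻⁴, 5]. Standard errors come
from the numerical Hessian of the Laplace log-likelihood; CIs are Wald;
AIC = 2k − 2ℓ with k counting fixed effects plus σ. The fit agrees with
`lme4::glmer` (nAGQ = 1) to ~4 decimals on identical data (tested), and
reduces to the plain logistic GLM as σ → 0. Quasi-separation (|β| > 15 on
the working scale) or optimiser failure is reported as `converged=False`
with a warning — never a silent estimate. The likelihood-ratio null is an
intercept + maturity fixed-effects-only logistic model.

Predicted probabilities use the fitted linear predictor including the
region's conditional-mode intercept; unseen regions fall back to the
population level with a warning.

## Problem sizes in tests and the acceptance script

The replicate study uses 200 simulated cohorts of n = 2000 (fitting both
models per cohort, ~1.5 min total); bias-direction checks use one default
cohort of n = 20,000; maturity recovery uses n = 500 noise-free players;
calibration uses 100,000 standard-normal draws. These sizes make Monte
Carlo error small relative to every tolerance tested while keeping the full
suite under a few minutes.

Recovery studies disable measurement noise, entry errors and birth-date
missingness, and resolve adult height exactly (policy `all`): they measure
the estimator and the fitter, not attenuation from noisy covariates. With
the default 0.5 cm noise and semester-6 adult heights, fitted maturity
coefficients attenuate by roughly 10–20% — visible in the default-cohort
coefficients the acceptance script also reports.

## Known limitations

* **Early saturation**: a player already at adult height at baseline has
  %AH = 100 regardless of *how* early they matured; biological age caps at
  the terminal age. The simulator's truth table flags such players
  (`clamped`).
* **Late-maturer inflation**: when adult height is taken from the
  sixth-semester measurement, players still growing at that point have
  underestimated adult height, hence inflated %AH and over-estimated
  maturity. For the default curve this bias exceeds 0.1 y of biological age
  once the timing offset is below about −2.5 y; a dedicated test
  demonstrates it. Real analyses handle such players by manual review or
  external adult heights; the pipeline surfaces them via the truth table
  and the recovered-height mechanism.
* The age-offset categories for players without birth dates inherit the
  cohort-default chronological age; their offsets are biased by the
  player's true deviation from that default.
* The Laplace approximation is accurate for large clusters (hundreds of
  observations per region, as here); with many tiny clusters adaptive
  quadrature would be preferable and is out of scope.
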