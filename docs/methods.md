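# Methods

## The composite risk model

Fourteen environmental risk factors for psychosis are binarized at fixed
cut-offs (winter birth Dec 21–Mar 20; gestational age < 37 weeks; birth
weight < 2500 g; ≥ 1 parent born in a non-Western country; > 1000
addresses/km²; lifetime cannabis use; bullied multiple times; "often" on ≥ 1
psychological-aggression item by either informant; physical abuse; sexual
abuse; paternal age > 35 years; parental divorce; lifetime parental severe
mental illness — major depressive, bipolar or psychotic disorder; parental
death). The weighted score adds the natural-log meta-analytic odds ratio of
every present factor; with the published 3-decimal weights the maximum is
9.18 (log-odds units). The unweighted ERS counts present factors (0–14).
Comparators: an 8-factor log-odds scheme (winter-or-spring birth 0.068 …
parental death 0.53; a ninth factor, neglect, has no data here) and a
6-factor integer-point scheme in which some *absent* states score negative
points (so its range includes −3 and no dose–response bands are defined for
it). An SMI-excluded variant (max 7.81) probes whether associations are
driven by familial/genetic liability.

Outcomes: PE = questionnaire total ≥ 6 (the boundary case is ambiguous in
common usage, so `pe_rule="gt"` is available; the default treats 6 as
positive); PS = clinician-rated flag; PE/PS = disjunction, decidable when at
least one component is observed (one observed negative with the other
missing counts as negative — the reading under which the combined analysis
sample exceeds both single-outcome samples, as in the study design the
generator emulates). Outcomes are never imputed.

Association models are logistic regressions adjusted for sex and baseline
age (a flag switches to follow-up age), fitted by IRLS with Wald CIs, the
standard output of mainstream statistical software for this design. The
continuous model uses the scaled score; bands (<1, 1–2, 2–3, 3–4, ≥4,
half-open, reference <1) are computed on the raw score, whose stated maximum
of 9.18 makes the ≥4 band a populated high-risk tail. Benjamini–Hochberg
correction is applied within each outcome's family of 20 tests (14 factors +
ERS + continuous PERS + 4 band terms); the family definition is
configurable because correcting across outcomes jointly is equally
defensible.

### Score scaling

The published analysis multiplies the weighted score "by 14" for
interpretability. Taken literally that maps the maximum to 128.5 and makes a
per-unit OR of ~1.4 implausible over the score's range; we therefore
implement the default scaling as ×14/Σw — the maximum maps to the factor
count, one scaled unit ≈ one average-weight factor, and the per-unit OR is
directly comparable to the ERS coefficient. The literal ×14 remains
available (`scaling_mode="literal"`) for auditability. Bands are unaffected
(raw score).

## Multiple imputation

Missing risk factors are imputed by chained equations (fully conditional
specification): m = 15 independent chains (distinct sub-seeds spawned from
one seed), 10 iterations each, hot-deck initialization, per-variable
Bayesian draws — logistic for binary indicators (coefficients drawn from the
approximate normal posterior, values drawn stochastically to preserve
between-imputation variance), Bayesian linear or predictive mean matching
(5 donors) for continuous variables. A failed conditional fit (separation,
singularity) falls back to PMM with a warning. The predictor matrix defaults
to all other risk factors plus sex and age; outcomes are excluded by default
(a conservative choice — the source analysis does not state its predictor
matrix — and a flag can include them). Estimates are pooled by Rubin's
rules, T = Ū + (1 + 1/m)B, with Barnard–Rubin small-sample degrees of
freedom; fit statistics (−2LL, Nagelkerke R²) are pooled as means over the
completed datasets, one reasonable convention among several. Pooling a
single fit returns it unchanged (B = 0), so an m = 1, no-missingness run
reduces exactly to the unpooled pipeline.

Nagelkerke pseudo-R² is computed against the intercept-only model,
`(1 − exp(2(LL0 − LL1)/n)) / (1 − exp(2·LL0/n))`, clipped to [0, 1].

## The synthetic cohort generator

No subject-level data accompany the design, so the generator is the test
bed: it emulates the *statistical structure* the analysis assumes, not any
real sampling frame.

- **Exposures.** The 14 binaries are dichotomized latent Gaussians
  (thresholds at the target margins — the study's descriptive-table
  prevalences, e.g. urban 78.7%, parental death 0.8%). Requested pairwise
  phi coefficients (default: gestational age × birth weight .57; a few
  adversity pairs .10, mirroring the reported "very low" remaining
  correlations) are hit by solving the copula correlation numerically
  (Brent's method on the bivariate-normal rectangle probability); the
  generator verifies each pair is feasible for its margins and that the
  joint latent matrix is positive definite, rejecting otherwise.
- **Raw columns.** Each binary truth is dressed in consistent raw
  measurements (truncated-normal gestational ages/birth weights/paternal
  ages, log-normal address densities, calendar birth dates uniform within or
  outside the winter interval, informant flags), so `binarize` recovers the
  generated truth exactly — the round-trip is a test oracle.
- **Selection.** A standard-normal screening score, latently correlated 0.3
  with the adversity factors, drives the oversampling design: the top 15%
  are retained with 2.5× the probability of the rest (accept–thin then
  simple random sample), giving the closed-form high-scorer share
  .15·2.5/(.15·2.5 + .85) ≈ .306. The 0.3 dependence is a disclosed
  assumption — the screening instrument's relation to the exposures is not
  specified anywhere — and is configurable.
- **Outcomes.** PE and PS are independent Bernoulli draws from one logistic
  model on the subject's true (pre-missingness) scaled score, default
  per-unit log-odds ln(1.38), with optional sex/age terms and an optional
  per-band effect for dose–response recovery studies. The questionnaire
  total is drawn consistently with the PE flag at the ≥6 cut-off. The
  default intercept (−3.283) was produced by the provided calibration
  helper, which solves E[1 − (1 − σ(η))²] = 21.5% (the study's combined
  prevalence) on a large simulated score distribution.
- **Missingness.** Per-variable MCAR masking at the study's rates
  (perinatal/paternal-age ≈ 29–35%, family/adversity 7–12%, ≤ 0.4%
  elsewhere; outcome masks 1.2%/9.0%), with an optional MAR mechanism
  conditioning on sex and age while preserving the overall rate. Outcome
  columns are refused by default.
- **Determinism.** One `numpy` Generator seeded from the spec; identical
  spec ⇒ byte-identical cohort.

What the generator does *not* emulate — item-level questionnaire structure,
attrition over waves, neighbourhood clustering, measurement error in
informant reports, real cohort-specific effect heterogeneity — bounds what
green tests show: they demonstrate the pipeline recovers known generating
parameters under the assumed structure, not that any particular cohort's
estimates are correct.

## Numerical choices and conventions

- Season boundaries fixed to the 21st regardless of year; Feb 29 is winter.
- A disjunctive indicator (ethnic minority, emotional abuse, combined
  outcome, any-adversity) is missing only when *all* its inputs are missing;
  one observed input decides presence (and, by our disclosed extension,
  absence).
- Scheme weights are stored at the printed 3-decimal precision so the 9.18
  maximum reproduces exactly; `full_precision=True` rematerializes ln(OR).
- The integer-point comparator's factors with unstated absent-points
  (paternal age 40–50, low birth weight, any adversity) score 0 when absent.
- Logistic fits use GLM/IRLS (pseudo-inverse), tolerating near-degenerate
  designs; coefficients > 15 in absolute value flag probable separation; a
  constant exposure column is dropped with a warning, reducing the model to
  covariates-only.
- Problem sizes in the test suite are chosen for tight Monte-Carlo error at
  desk scale: margins and correlations at n = 20 000, parameter recovery at
  n = 20 000 (3-SE criterion), CI coverage over 200 replicates of n = 400
  with m = 5, type-I error over 200 null replicates of n = 500.

## Known limitations

- Additivity on the log-odds scale is assumed throughout, as in the source
  model; no interactions or factor correlations enter the score.
- The imputer handles binary and continuous conditionals only (no ordinal or
  multinomial models); that covers every variable this pipeline imputes.
- Published cohort-specific odds ratios are not reproducible without the
  original data; the package instead demonstrates parameter recovery on
  synthetic cohorts generated at the published effect sizes.
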