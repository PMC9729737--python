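# Methods

## The analysis model

A participant's day is a 4-part composition **x** = (sleep, SB, LPA, MVPA)
in minutes, closed to 1440. Because only the relative information in **x**
is meaningful (the parts are exhaustive and sum to a constant), regression
works in isometric log-ratio (ilr) coordinates. With part order
(x₁, …, x₄) the pivot coordinates are

  z_k = √((4−k)/(4−k+1)) · ln( x_k / g(x_{k+1}, …, x₄) ),  k = 1, 2, 3,

where g(·) is the geometric mean. z₁ contrasts the first part against the
remaining three ("behaviour vs remaining"); the default order is (sleep,
SB, LPA, MVPA). The outcome model for each cognitive score y is ordinary
least squares:

  y = β₀ + βᵀz + γᵀc + Σ_m δ_mᵀ(z × m) + ε,

with covariates c = {age, sex, site, education years, smoking status},
moderator main effects m ∈ {TV-watching tertile, recreational-PA category,
sleep quality}, the 3-df composition block z, and optional 3·(levels−1)-df
composition × moderator interaction blocks. Categorical terms are
dummy-coded against the references male / Adelaide / never-smoker / good
sleep / low TV / over-30-min recreational PA. Assumptions are those of
linear regression on ilr coordinates: linearity of the outcome in the
log-ratios, homoscedastic Gaussian errors, and strictly positive
compositions (no zero-replacement is performed; a zero behaviour average
in device data is treated as an input error).

## Inference procedure

1. **Backward selection** starts from the full model. Interaction blocks
   are tested with type II F-tests and removed one at a time in order of
   largest p while that p ≥ α = 0.05 (ties broken in the fixed order TV,
   recPA, sleep quality). The composition block is then tested and removed
   if p ≥ α — but only when no interaction block remains (marginality).
   Finally the covariates and moderator main effects are tested with one
   collective F. By default that block is always retained, because the
   reference output this package mirrors reports clearly non-significant
   covariates inside final models; `drop_covariates=True` switches to
   strict removal. Every decision is recorded in a selection trace, and a
   test asserts the trace never violates marginality.
2. **Type II F-tests** on the final model: for term group g, SS_g is the
   RSS drop when g is added to the model containing every term except g
   and except any term containing g; F = (SS_g/df_g) / MSE(full model),
   with the full model's residual df in the denominator. Composition and
   interaction blocks are tested jointly as multi-df groups. The
   implementation computes RSS via least squares on column subsets of the
   design; the test suite checks it against an independent brute-force
   path (explicit statsmodels refits of both nested models) to 1e-8
   relative on 50 random cohorts.
3. **FDR**: Benjamini–Hochberg adjustment is applied to the term p-values
   within each outcome's final model — the family is the set of terms of
   one model, a reading verified by reproducing the printed adjusted
   p-values of a published final model from its printed raw p-values.
   Note BH is not idempotent: re-adjusting already-adjusted values
   rescales them again, so only monotonicity and order preservation are
   asserted as invariants.
4. **Pivot slopes**: the final model is refit under the four part orders
   placing each behaviour first; the first coordinate's coefficient is the
   behaviour-vs-remaining slope. The four rotations are orthonormal
   changes of basis, so fitted values and R² are identical across refits
   (asserted to 1e-9). Analytically, the pivot slope of part i equals
   (2/√3)·θ_i where θ = Ψᵀβ is the clr coefficient vector — used as the
   closed-form truth in recovery simulations.

## Accelerometry processing

Inputs are 1-min epoch activity values ("g-min") with diary sleep
intervals. Rules, in order:

- **Non-wear**: maximal runs of ≥ 60 consecutive epochs at ≤ 25 g-min.
- **Classification** with precedence sleep > non-wear > intensity; waking
  epochs: MVPA > 93 g-min, LPA 48–93 g-min, SB ≤ 48 g-min. The published
  bands "<48" and ">48 / >93" leave 48 and 93 unassigned; exactly 48 is
  classified SB and exactly 93 LPA, keeping the bands disjoint and SB the
  default waking state.
- **Valid day**: waking wear time (1440 − sleep − non-wear) ≥ 600 min;
  diary sleep is trusted over epoch values. Day type (weekday/weekend)
  comes from the input record, not calendar parsing.
- **Valid week**: ≥ 3 valid weekdays and ≥ 1 valid weekend day; failing
  participants are a typed exclusion, not an exception.
- **Averaging**: behaviour minutes are averaged over valid days only, then
  the four behaviour means are closed to 1440, redistributing mean
  non-wear proportionally. Closure happens after averaging (not per day)
  so that averaging operates on observed minutes.

## Cognitive outcomes

Global cognition is the raw ACE-III total (0–100), never z-scored — it is
its own interpretable scale. The four domain composites (long-term memory,
short-term memory, executive function, processing speed) are unweighted
means of component z-scores (sample mean/SD with the n−1 denominator),
after sign-reversing measures where lower is better. "Unweighted mean" is
a choice: the source describes collation into composites without a
formula, and the equal-weight mean is the standard construction. A
composite is missing unless every component is present and every
accuracy-based inclusion rule is met (accuracy strictly below 50% masks
the participant from the affected composites only). The exact rule list of
the original battery is not public; rules are therefore configuration
(`InclusionRule`), with per-test 50%-accuracy gates as the default.

## The synthetic cohort

The generator produces the statistical structure the analysis assumes:

- **Compositions**: logistic-normal — multivariate normal on the ilr
  scale, centred at the ilr image of the mean composition, mapped back and
  closed to 1440. Default centre (503, 668, 178, 89) min closed; default
  ilr covariance diag(0.03, 0.06, 0.25). The source study reports no
  second moments on the log-ratio scale, so the covariance is a stated
  package default (ordered to mirror the observed coefficient-of-variation
  pattern: sleep tight, LPA:MVPA balance loose), not an estimate of any
  cohort. Because the logistic-normal is right-skewed on the simplex,
  arithmetic part means of generated samples sit a few minutes away from
  the closed centre; the compositional (geometric) mean matches it by
  construction.
- **Covariates**: age truncated-normal 65.5 ± 3.0 on [60, 70] (the
  eligibility window; truncation rather than resampling for determinism);
  education normal 16.5 ± 3.2 clipped at 0; TV minutes a three-component
  normal mixture (44/126/224 ± 30/20/59, clipped at 0); recreational-PA
  minutes 0 for "none", truncated-normal within (0, 30] and (30, ∞) for
  the other categories. Categorical covariates (sex, site, smoking,
  sleep-quality rating, recPA category) are drawn by exact-proportion
  allocation with random assignment: the emulated marginals are fixed
  published sample counts, and exact allocation both matches them and
  guarantees rare categories (2% previous smokers) appear in every cohort
  so dummy columns are never empty.
- **Outcomes**: y = β₀ + βᵀz + γᵀc (+ interactions) + N(0, σ²), the exact
  data-generating twin of the analysis model. Null and alternative
  scenarios differ only in the coefficient fields.
- **Epoch weeks**: per-day class-minute targets are materialised as
  contiguous blocks of epochs drawn uniformly inside each label's
  cut-point band (SB in (25.5, 48], LPA in (48.5, 93], MVPA in (93.5,
  500]; the 500 g-min cap is arbitrary — only the band matters). Sleep and
  non-wear epochs are low-valued (≤ 25); non-wear is a single contiguous
  run, so a target in (0, 60) min is rejected as unrealisable. The
  construction round-trips exactly through the accelerometry pipeline.

What the generator does **not** emulate: circadian or bout structure
within the day, autocorrelated epoch noise, measurement error in the
diary, correlated covariates (age/education/activity are independent
draws), informative missingness, or any genuine composition–cognition
effect structure of real cohorts. Passing tests therefore demonstrate that
the pipeline's arithmetic, rules and inferential procedure are correct and
calibrated under the assumed model — not that the scientific findings of
any real data set would be reproduced.

## Numerical choices

- Closure, ilr and reallocation identities are asserted at 1e-9 relative;
  type II oracle equivalence at 1e-8 relative; minute conservation at
  1e-6.
- Rank-deficient designs raise an error naming the aliased columns
  (QR with column pivoting); listwise deletion per outcome defines the
  complete-case n reported with every model.
- TV tertiles use linear-interpolation empirical quantiles at 1/3 and 2/3;
  values exactly at a cut go to the lower category. Recreational PA of
  exactly 30 min falls in the "up to 30" category; sleep-quality ratings
  0–1 are "good", 2–3 "bad".
- Reallocation grids truncate (and flag) rather than error at the simplex
  boundary; the confidence band on prediction curves is the delta-method
  band x'Σ̂x from the coefficient covariance with the model's residual df
  — the band construction for these curves is not specified by the source
  and is documented here as the package's choice.
- Demographic percentages are recomputed from counts and rounded
  half-away-from-zero.

## Simulation sizes

The validation experiments run at: 1000 replicate cohorts of n = 384 for
the null calibration of the composition F-test (95% binomial band
0.036–0.064 around α = 0.05); 150 replicates for the backward-selection
null behaviour; n = 5000 for 3-standard-error coefficient recovery; and
n = 20 000 with σ = 0.25 for the pivot-slope recovery reported by the
acceptance script, sized so the Monte-Carlo SE (≈ 0.01) sits below the
two-decimal reporting resolution.

## Known limitations

- The inference engine assumes complete separability of the moderator
  dummies from the composition block; heavily unbalanced moderators in
  small samples can alias interaction columns (reported, not worked
  around).
- No mixed models, survey weights or multiple imputation; missingness is
  handled by listwise deletion per outcome.
- The accelerometry module starts from 1-min epochs: raw 100-Hz signal
  processing, auto-calibration and sleep detection are out of scope, and
  diary sleep intervals are taken as ground truth.
- BH adjustment is applied within each outcome's final model; other
  family definitions (e.g., across outcomes) would give different adjusted
  values.
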