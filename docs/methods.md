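# Methods

## Model

Observed body weight (kg) is modelled as

    Y = μ + G_i + P_j + PS_k + Σ_l b_l·X_l + Σ_l b_l(G_i)·X_l + F_m + ε

- `G_i`: genotype class.  Fleckvieh cows are subclassed by Red-Holstein
  gene proportion (≤10 % → FV, >10–44.5 % → FV×RH_m, >44.5 % → FV×RH_h);
  Holstein-Friesian and Brown Swiss are single classes.  Brown Swiss is
  the reference (zero effect, zero slope deviations).
- `P_j`: parity class 1, 2, 3+4 or ≥5; the oldest class is the reference.
- `PS_k`: physiological stage, 13 four-week lactation classes covering
  DIM 1–364 and four two-week dry stages covering days −56…−1 relative
  to the next calving.  Day 0 and days beyond the fitted range are
  rejected rather than extrapolated, because polynomial curvature outside
  the data range is not trustworthy.  (The lactation domain is taken as
  1–364: thirteen 28-day classes cover exactly 364 days, and that is the
  maximum day the descriptive profiles contain.)
- `b_l`, `b_l(G_i)`: pooled and genotype-specific linear regressions on
  body measurements in cm.  With reference coding the pooled slope is the
  Brown Swiss slope and the deviations are per-genotype additions.
- `F_m ~ N(0, σ²_farm)`: random farm intercept; `ε ~ N(0, σ²_res)`.

No per-cow random effect is fitted; repeated records of a cow are
conditionally independent given the farm.  (Including a cow effect makes
the mixed-model equations at this design size impractical and is not part
of the modelled structure.)  Quadratic measurement terms are supported
behind a flag for model comparison but are excluded from assembled
prediction equations; they do not improve girth-based equations
appreciably.

## Two-stage estimation

1. **REML mixed model** (`fit_mixed`): the categorical-stage model above
   is estimated by REML via `statsmodels` `MixedLM` with a single
   variance component for farm.  The model RMSE is the square root of the
   estimated residual variance.  AIC is reported as −2·logL + 2·(p + 2)
   with p fixed effects plus the two variance parameters.
2. **Stage curves** (`stage_lsm`, `fit_stage_curves`): least-squares
   means of the 17 stage classes are computed at equal weights for the
   genotype and parity classes (1/5 and 1/4), covariates at their grand
   means (covariate-by-genotype columns therefore at mean/5), farm effect
   zero — the default convention of the standard mixed-procedure
   LSMEANS, chosen so an external cross-check can match it.  A degree-4
   polynomial in DIM (lactation) and a line (dry) are fitted to the LSMs
   by OLS at the class midpoint days (14.5, 42.5, …, 350.5; −49.5,
   −35.5, −21.5, −7.5).  Midpoints are the symmetric choice of
   representative day; the abscissae are overridable.  The per-period
   curve RMSE (root mean square of the 13 resp. 4 fit residuals) is
   reported alongside.
3. **Assembly** (`assemble_prediction_model`): the categorical stage
   effects are replaced by the fitted curves.  The curves live on the LSM
   scale (intercept + averaged class effects + grand-mean covariate
   term); that constant is subtracted from the intercept so that
   intercept + curve(day) reproduces the categorical prediction at each
   class's representative day up to the curve residual.  Only the *sum*
   of intercept and curve constant is identified — any constant can be
   moved between them without changing predictions — so recovery checks
   compare effects, slopes, stage contrasts and the composite prediction
   function, not the two constants separately.

Stepwise evaluation (`stepwise_evaluate`) fits a list of candidate
measurement sets and ranks them by RMSE with AIC reported alongside,
ties broken toward fewer measurements; failed fits are recorded per
candidate rather than aborting the comparison.

## Validation

`split_every_fifth` sorts by cow id, then day (then input order, making
the order total) and sends every fifth record to the hold-out subset —
the deterministic 80/20 rule that spreads validation records evenly over
farms, cows and stages.  A cow-level splitter is provided for simulation
studies where leakage across subsets matters.

`mspe_decompose` uses population (divide-by-n) moments so that

    ECT + ER + ED = (Ō−P̄)² + (s_P − r·s_O)² + (1−r²)·s_O² = MSPE

holds as an exact identity (the denominators must match for the
cross-terms to cancel; with sample variances the sum misses MSPE by
O(1/n)).  R² is the squared Pearson correlation of observed and
predicted.  `stpierre_regression` regresses residuals on mean-centered
predictions; its intercept equals the mean bias and its slope equals
cov(O,P)/var(P) − 1, and both closed forms are asserted against the
numerical OLS solution on every call.  Reports are produced separately
for lactation and dry periods, assigned from the record's day, with
percentages carried to three decimals.

## Synthetic herds

The generator (`simulate_herd`) emulates the structure of the reference
population: 167 farms; genotype mixture 41.3 / 12.3 / 5.9 / 16.7 /
23.8 % (FV / FV×RH_m / FV×RH_h / HF / BS); parity drawn from a truncated
geometric distribution on 1–13 calibrated to mean 3.0; each record dry
with probability 0.10 (the observed dry-to-lactation record ratio),
stage day uniform over the period's domain; measurements drawn from a
period-specific truncated multivariate normal whose means, SDs,
truncation bounds and correlation matrices are the published descriptive
profiles of that population (e.g. lactation heart girth 210 ± 10.3 cm,
truncated to 173–253 cm; heart–belly girth correlation 0.72).  Body
weight is generated from a packaged coefficient set plus farm effect and
Gaussian residual; realized farm effects and residuals are stored so the
generative identity can be verified record by record.

Defaults that the source material does not pin down, chosen once:

- **Farm-effect SD 20 kg.**  Not reported for the original data; 20 kg
  is a plausible between-herd spread, far below the residual scale, and
  the estimation checks are insensitive to it.
- **Residual SD = the packaged equation's estimation RMSE** (30.4 kg for
  Model_HGBGHW, 32.5 kg for Model_HGBG), so a correctly specified refit
  should recover exactly that value.
- **Measurements independent of day.**  Real belly girth drifts upward
  through lactation; no within-lactation trajectory is parameterized in
  the source profiles, so none is simulated (an optional hook would be a
  natural extension).  Consequently the simulated stage effect is the
  only day-dependence in generated weights.
- **RH gene fraction** is drawn uniformly within the class interval and
  is informational only; the class label drives the model.

Truncation is record-level rejection sampling from the Cholesky
factorization of the (repaired) correlation matrix, with a round cap
that turns infeasible bounds into a configuration error.  The bounds sit
3.5+ SDs from the means, so acceptance per draw is high and the
truncation bias on means, SDs and correlations is far below the ±0.03
tolerance the generator is tested to.

`repair_correlation` projects a printed correlation matrix onto the
nearest PSD correlation matrix (via `statsmodels`' Higham-style
`corr_nearest`) before use; both packaged period matrices are PSD as
printed, so the repair is the identity for the defaults, and the
projection result is re-checked for PSD-ness.

What passing tests on these herds do **not** show: performance on real
records with measurement error in the tape/stick readings, observer
effects in BCS, within-cow repeated-measures correlation, seasonal and
within-lactation measurement trends, or non-Gaussian residuals.  The
generator validates the machinery, not the biology.

## Numerical choices

- **Noise-free inputs**: with zero residual and farm variance the REML
  problem is singular, so `fit_mixed` detects a near-zero OLS residual
  SD (< 1e−6 kg) and returns the exact least-squares solution with zero
  variance components.  In that limit all identified coefficients are
  recovered to ≤1e−6 when days sit at class midpoints (the
  `days_at_class_midpoints` generator flag), since then the generating
  stage term is constant within each class.
- **Optimizer fallbacks**: the default gradient optimizer occasionally
  stalls on flat variance profiles (notably for single-measurement
  models); `fit_mixed` retries with Powell and Nelder–Mead and only then
  raises a fit error carrying the per-attempt diagnostics.
- **Polynomial conditioning**: stage curves are fitted in day/100 and
  the coefficients rescaled exactly, keeping the degree-4 Vandermonde
  well conditioned over DIM 1–364 (coefficients span ten orders of
  magnitude on the raw scale).
- **Serialization**: coefficient sets are written as YAML with floats
  rendered via `repr`, and record CSVs are written with `repr` floats
  and read with round-trip parsing, so both round-trip bit-exactly.
- **Degrees of freedom**: fixed-effect P-values (Kenward–Roger in the
  usual mixed-procedure workflow) are out of scope; the package reports
  estimates, RMSE and AIC and leaves hypothesis-test formatting to the
  user.
- **Reference coding**: Brown Swiss, parity ≥5 and the first lactation
  month are the baselines.  A fit fails loudly, naming the class, if any
  genotype, parity or stage class is empty.

## Problem sizes

The packaged analyses and checks use 20 000-record herds for parameter
recovery and hold-out validation (ten seeds for the disturbance-share
summary), 10 000 records for the narrative drivers and moment checks,
and 4 000–6 000 records for unit-level fitting tests; at these sizes a
REML fit takes well under a second and every reported quantity is stable
to within its stated tolerance across seeds.

## Known limitations

- Predictions are population-level (farm effect zero); farm-level BLUPs
  are not currently exposed.
- The dry-period day is relative to the *next* calving, which requires a
  (predicted) calving date in prospective use.
- Equations are fitted to cows within the measurement profiles above;
  extrapolation to heifers, other breeds, or measurements outside the
  truncation ranges is unsupported (and out-of-domain days are rejected
  outright).
- The packaged lactation polynomial of Model_HGBGHW is carried exactly
  as published; its linear term is implausibly small relative to the
  shape the accompanying description implies (a typographical slip in
  the source cannot be ruled out), so no claim is made about the curve's
  interior minimum.
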