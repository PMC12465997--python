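# Statistical methods

This note records the models implemented in `btexmix`, the estimators
used, and the reasoning behind the main numerical and design choices.
Notation: Y* is latent (untreated) HbA1c, Y is observed HbA1c, X is the
quartile-coded exposure, Z the adjustment covariates, and M a binary
medication indicator at a given visit.

## 1. Outcome model: censored-normal (Tobit) regression

### The censoring structure

Glucose-lowering medication lowers HbA1c by an unknown, person-specific
amount, so for a medicated participant the observed value is a lower
bound: Y* ≥ Y. Each such observation is right-censored *at its own
observed value* — there is no common censoring threshold. Untreated
participants contribute their latent value exactly.

The model is linear with homoscedastic normal errors on the latent
scale: Y* = x'β + ε, ε ~ N(0, σ²). With censoring flag c ∈ {0,1} and
per-observation weight w, the log-likelihood is

```
ℓ(β, log σ) = Σᵢ wᵢ [ (1−cᵢ) · log φ((yᵢ − xᵢ'β)/σ)/σ
                      +  cᵢ   · log Φ̄((yᵢ − xᵢ'β)/σ) ]
```

where Φ̄ = 1 − Φ is the normal survival function: a censored row says
only that the latent value exceeds yᵢ.

### Three analysis equations

- **eq1** — initial HbA1c (home visit) on exposure quartiles and Z;
  censored if medicated at the home visit (`med_hv`); weight w_hv.
- **eq2** — final HbA1c (clinical exam) on exposure and Z plus both
  exposure-duration terms; censored if medicated at the exam (`med_ce`);
  weight w_hv·w_ce.
- **eq3** — final HbA1c adjusted for initial HbA1c and their product;
  participants already medicated at the home visit are *artificially
  censored* — dropped from the fit — because their initial HbA1c (now a
  regressor) is itself censored and would carry its bias into the
  design matrix. The remaining rows are censored on `med_ce` and
  weighted by w_hv·w_ce, which re-weights the retained sample toward the
  full eligible cohort.

### Optimization and covariance

The likelihood is maximized over (β, log σ) — the log-σ parameterization
keeps the scale positive and the surface well-conditioned — by BFGS
followed by a Newton polish using the analytic Hessian. Per-row Hessian
contributions use the hazard h = φ/Φ̄ of the standardized residual z and
h′ = h(h − z):

- uncensored: ∂²ℓ terms (−1/σ², −2z/σ, −2z²) for (ββ, βσ, σσ) blocks,
- censored: (−h′/σ², −(zh′ + h)/σ, −(z²h′ + zh)).

Both the model-based covariance (inverse negative Hessian) and a
sandwich (robust) covariance from per-row scores are computed. The
sandwich form is the default exactly when non-unit weights are supplied:
IPCW weighting makes the working likelihood a pseudo-likelihood, for
which the information equality fails and the model-based variance is
inconsistent. With unit weights the model-based variance is used.

Degenerate inputs raise errors rather than returning garbage: all rows
censored, rank-deficient designs, and negative weights are rejected; a
count of rows dropped for missing values is reported.

The implementation is validated in the test suite against closed-form
likelihood values, a brute-force grid-search oracle, weighted least
squares in the no-censoring limit (agreement to 1e-6), and R's
`survival::survreg` as an independent oracle.

## 2. Exposure quantization

Cutpoints are empirical quartiles (the standard linear-interpolation
quantile definition, "type 7") fitted once on the analysis sample and
frozen; scoring assigns bin j ∈ {0,1,2,3} with values equal to the lower
cutpoint mapped to the *lower* bin, so exact boundary values are
reproducible. Scores are used two ways: as three indicator contrasts
(q2, q3, q4 vs. the lowest quartile) in single-exposure models, and as
integer scores in the mixture model. Cutpoints are refit per imputed
dataset only if exposure were imputed; exposures are never missing in
this design, so cutpoints are identical across imputations (this is
asserted in tests).

## 3. Mixture effect: quantile g-computation

All four chemical quartile scores enter one weighted Tobit fit jointly.
The mixture effect is

```
ψ = Σ_k β_k ,   Var(ψ) = 1'Σ1
```

summing over the four score coefficients, with Σ the exposure block of
the coefficient covariance. ψ is the modeled change in latent HbA1c when
every chemical rises one quartile simultaneously — a policy-style
contrast that sidesteps the instability of single-pollutant coefficients
under rank correlations above 0.9. Component "shares" split the
coefficients by sign and normalize within each sign class, showing which
chemicals drive the positive and negative parts of ψ. If every
coefficient is exactly zero the shares are undefined and an error is
raised. The aggregate total-BTEX variable is excluded from the joint fit
by construction (it is collinear with its components); mixing chemicals
quantized with different q is rejected. A percentile bootstrap
(`bootstrap_psi`, row resampling with fixed cutpoints) provides a
non-delta-method interval check.

## 4. Informative censoring: stabilized IPCW

Medication initiation depends on covariates that also predict HbA1c, so
the censoring in §1 is informative. Weights restore the uncensored
covariate distribution:

```
w = P(M = 0 | age, BMI) / P(M = 0 | full covariates)
```

Both models are binomial GLMs with logit link. The stabilized numerator
(age + BMI rather than intercept-only) shrinks the weight spread while
leaving the estimand unchanged, since age and BMI are already in every
outcome model. The clinical-exam weight w_ce is fitted among
participants still untreated at the home visit (the relevant risk set);
HV-treated participants receive w_ce = 1. Predicted untreated
probabilities below a floor of 0.01 are either truncated or raise an
error (configurable); optional percentile truncation of the final
weights is available. Near-perfect separation in the treatment model is
detected (fitted probabilities within 1e-10 of 0 or 1) and reported with
the offending term name, rather than silently yielding extreme weights.

Scheme application (`apply_censoring_scheme`) returns, per equation, the
analysis rows, censor flag and combined weight described in §1.

## 5. Missing covariates: chained-equations imputation and pooling

Covariates with missingness (smoking, education, BMI, and similar) are
imputed m = 14 times by chained equations: predictive mean matching with
5 donors for continuous variables, multinomial-logistic draws for
categoricals (predictors standardized before fitting for conditioning;
ridge penalty effectively off at C = 1e4). Exposures, outcomes,
medication flags and durations are never imputed — they are structurally
complete — and observed values are never altered.

Each imputed dataset gets the full analysis (weight models refitted,
Tobit refitted), and estimates are pooled by Rubin's rules:

```
q̄ = mean(qₘ),  ū = mean(SEₘ²),  b = var(qₘ),  t = ū + (1 + 1/m) b
```

with Barnard–Rubin degrees of freedom for the t-interval and the
fraction of missing information (fmi) reported. Zero between-imputation
variance (no missingness) collapses to the single-fit answer exactly.

## 6. Synthetic cohort generator

No individual-level data ship with the package, so validation uses a
generator with known ground truth:

- **Exposures.** A Gaussian copula (default pairwise rank correlation
  0.95) produces four uniform ranks; each rank maps to a chemical
  concentration by linear interpolation of log-concentration against the
  normal quantile (z) of published anchor quantiles. Interpolating in
  z-space rather than rank-space makes the implied distribution locally
  log-normal between anchors and keeps the tails finite and plausible.
  Quartiles of each chemical and of the aggregate total reproduce their
  targets within 10% relative error at n = 10,000 (tested; observed
  maximum error ≈ 2%).
- **Covariates.** Age, BMI, sex, race, education, employment, smoking,
  insurance and area-deprivation quartile are drawn to match published
  cohort marginals (e.g. mean age ≈ 45.8 years, mean BMI ≈ 30, 40%
  Black participants).
- **Outcomes.** Latent initial and final HbA1c are bivariate normal
  around a covariate-dependent mean (tracking correlation 0.7, residual
  SD 0.85), with configurable quartile effects injected on the latent
  scale. The default effect on total BTEX is the inverted-U
  (0.24, 0.13, 0.00) for (Q2, Q3, Q4) vs. Q1; the default joint mixture
  effect is null.
- **Medication.** Initiation is a logistic function of latent HbA1c (so
  treated participants really do have high latent values) with monotone
  visits (med_ce ≥ med_hv); treated participants' observed HbA1c is the
  latent value minus a log-normal reduction (median 0.8), floored so
  medication cannot push HbA1c below a physiologic bound. Untreated
  participants observe their latent value exactly.
- **Missingness.** MCAR or MAR (probability increasing in age) at
  configurable per-column rates (capped), never on structurally complete
  columns. `real_data_mode` drops all latent-truth columns to mimic a
  field dataset.

Everything is driven by a single integer seed through `numpy`'s
`default_rng`; identical configs produce byte-identical cohorts.

**Limits.** The generator is a calibration device, not a disease model:
covariates are mostly independent of exposure unless `confounder_strength`
is set, effects are linear on the latent scale, and the copula imposes a
single exchangeable rank correlation.

## 7. Pipeline

`run(config)` executes: load or simulate → eligibility exclusions
(sequential, order-fixed: invalid aliquot, no clinical exam, missing key
covariates, rig worker) → imputation → per-cell (model × exposure ×
stratum) weighted Tobit analyses → pooling → CSV results plus a JSON
manifest recording counts at every stage (input, eligible, censored,
eq3-retained), a config hash, and any failed cells. Stage counts satisfy
conservation identities that the tests assert. The CLI exposes
`simulate`, `analyze` and `report`; configuration errors exit with code
2, analysis failures with 1.

## 8. Numerical conventions

- 95% intervals use z = 1.959963984540054 (normal) or the
  Barnard–Rubin t quantile for pooled results.
- All randomness flows from explicit integer seeds; no global RNG state.
- Design matrices support numeric columns, `C(col)` dummy expansion with
  a fixed canonical reference level, and `a:b` numeric products — a
  deliberately small mini-language so every design is auditable.
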