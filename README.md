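# btexmix

Censored-outcome Tobit regression, quantile g-computation, and
inverse-probability-of-censoring weighting (IPCW) for studying a
quartile-coded mixture of volatile aromatic hydrocarbons — benzene,
toluene, ethylbenzene and xylenes (BTEX) — in relation to glycated
hemoglobin (HbA1c), with a calibrated synthetic cohort generator and
Rubin's-rules pooling over multiply-imputed data.

## The scientific problem

Workers involved in a large oil-spill cleanup were exposed to airborne
BTEX for weeks to months. Years later their HbA1c — a long-run marker of
glucose control — was measured at a home visit and again at a clinical
exam. Estimating the exposure–HbA1c association from these data raises
three intertwined problems:

1. **Medication censors the outcome.** Participants who started
   glucose-lowering medication before a visit have an observed HbA1c that
   is *at most* their latent (untreated) value. Their latent HbA1c is
   right-censored at the observed value, with a censoring point that
   differs per person. Ordinary least squares on observed values is
   biased toward the null; the package fits a weighted censored-normal
   (Tobit) likelihood with observation-specific right-censoring instead.

2. **Medication initiation is informative.** Who starts medication
   depends on covariates that also predict HbA1c, so censoring is not
   random. The package computes stabilized inverse-probability-of-
   censoring weights: the numerator models remaining untreated given age
   and BMI, the denominator given the full covariate set. Three analysis
   schemes are supported — `eq1` (initial HbA1c, home-visit medication),
   `eq2` (final HbA1c, clinical-exam medication), and `eq3` (final HbA1c
   adjusted for initial HbA1c, with participants already medicated at the
   home visit artificially censored, i.e. dropped, because their initial
   HbA1c is itself censored).

3. **The exposures are a highly correlated mixture.** The four chemicals
   are rank-correlated above 0.9, so single-pollutant coefficients are
   hard to interpret. Each chemical is coded into quartile scores
   (0,1,2,3) and the joint mixture effect is estimated by quantile
   g-computation: ψ, the expected change in HbA1c when every chemical
   moves up one quartile simultaneously, is the sum of the four score
   coefficients, with variance **1**'Σ**1** over the exposure block of the
   covariance matrix.

Covariate missingness is handled by multiple imputation (chained
equations, m = 14 by default); estimates are combined with Rubin's rules
and Barnard–Rubin small-sample degrees of freedom. Because no real cohort
ships with the package, a synthetic generator produces cohorts calibrated
to the published exposure quantiles and covariate marginals, with known
ground truth for validation.

## Worked example (library API)

```python
from btexmix import (GeneratorConfig, generate_cohort, stabilized_weights,
                     fit_cutpoints, fit_qgcomp_tobit)
from btexmix.config import CHEMICALS

cfg = GeneratorConfig(n_participants=2541, seed=7)
df = generate_cohort(cfg)

# stabilized inverse-probability-of-censoring weights for medication
w = stabilized_weights(df)
df["cens"] = df["med_ce"].astype(float)   # latent HbA1c >= observed if medicated

# quartile cutpoints per chemical; the joint mixture effect (psi)
specs = {c: fit_cutpoints(df[c].to_numpy(), q=4, chemical=c) for c in CHEMICALS}
mix = fit_qgcomp_tobit(df, quant_specs=specs,
                       covariates=["age_months", "bmi", "C(smoking)",
                                   "duration1", "duration2"],
                       outcome="hba1c_final", censor_flag="cens",
                       weights=(w.w_hv * w.w_ce))
print(f"psi = {mix.psi:.3f}  (95% CI {mix.ci_low:.3f}, {mix.ci_high:.3f})")
print("positive-direction shares:",
      {k: round(v, 2) for k, v in mix.component_shares()["positive"].items()})
```

Output (this is real output; the default generator injects a null mixture
effect, and the confidence interval correctly covers zero):

```
psi = -0.014  (95% CI -0.046, 0.019)
positive-direction shares: {'toluene': 0.67, 'xylenes': 0.33}
```

Single-exposure quartile contrasts come from `fit_tobit` plus
`contrasts`; `parse_formula("hba1c_final ~ q2 + q3 + q4 + age_months",
censor_flag="cens")` builds the same `ModelSpec` from a formula string.

## Worked example (command line)

Simulate a cohort:

```
$ btexmix simulate --n 1000 --seed 7 --out cohort.csv
wrote 1000 participants to cohort.csv (seed=7, med_hv=11.4%, med_ce=17.5%)
```

Run a full pooled analysis from a YAML config:

```yaml
# cfg.yaml
generator: {n_participants: 2541, seed: 7}
pooling: {m_imputations: 14, seed: 1}
analyses:
  models: [eq3]
  exposures: [total_btex]
  strata: [none]
output: results
```

```
$ btexmix analyze cfg.yaml
{
 "config_hash": "625f074e461019dc",
 "seed": 7,
 "version": "0.1.0",
 "n_input": 2541,
 "n_eligible": 2541,
 "n_eq3_retained": 2247,
 "n_censored_hv": 294,
 "n_censored_ce": 479,
 "elapsed_seconds": 7.8,
 "outputs": [
  "results/results.csv",
  "results/resolved_config.yaml"
 ],
 "failed_cells": []
}

$ btexmix report results/results.csv
model stratum   exposure      contrast  estimate  ci_low  ci_high    n
  eq3    none total_btex total_btex_q2     0.235   0.165    0.306 2247
  eq3    none total_btex total_btex_q3     0.112   0.040    0.185 2247
  eq3    none total_btex total_btex_q4    -0.042  -0.110    0.027 2247
```

The generator's default total-BTEX quartile effects are (0.24, 0.13,
0.00) on latent final HbA1c — the pooled, weighted `eq3` analysis above
recovers the injected inverted-U pattern. Reruns with the same config are
byte-identical. Exit codes: 0 success, 1 analysis failure, 2 bad
configuration.

## Reproduction

Run the test suite (includes slow simulation-based calibration checks;
roughly 12 minutes on one CPU):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Run the end-to-end report of the pipeline's main computed quantities
(about half a minute):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The JSON maps each quantity to `{"value": ..., "n": ...}`: treated
fractions, weight diagnostics, pooled eq3 total-BTEX quartile contrasts
and half-widths, the pooled eq2 mixture ψ, and the generator's
exposure-quantile calibration error.

## Layout

| Path | Contents |
| --- | --- |
| `src/btexmix/cohort.py` | synthetic cohort generator and missingness injection |
| `src/btexmix/quantize.py` | quartile cutpoints, scores, indicator coding |
| `src/btexmix/tobit.py` | weighted Tobit MLE with per-observation right censoring |
| `src/btexmix/weights.py` | stabilized IPCW and the eq1/eq2/eq3 censoring schemes |
| `src/btexmix/qgcomp.py` | quantile g-computation mixture effect ψ and bootstrap |
| `src/btexmix/pooling.py` | chained-equations imputation, Rubin's-rules pooling |
| `src/btexmix/pipeline.py`, `cli.py` | end-to-end orchestration and the `btexmix` CLI |
| `docs/methods.md` | statistical methods note |

See `docs/methods.md` for the model equations, likelihood, and the
reasoning behind each methodological choice.
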