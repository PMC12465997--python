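"""Quantile g-computation on a censored-regression base model.

All four quantized exposures enter one weighted Tobit model as linear
integer scores (0..3). Under the linearity/additivity assumption the
mixture effect psi -- the mean latent-outcome change per simultaneous
one-quartile increase in every component -- is the sum of the four score
coefficients, with delta-method variance 1' Sigma 1 over the exposure block
of the coefficient covariance. Signed per-chemical shares of psi follow the
usual quantile g-computation weight convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantize import QuantizationSpec, score
from .tobit import ModelSpec, TobitFit, Z_95, fit_tobit


@dataclass
class MixtureEstimate:
    psi: float
    se: float
    ci_low: float
    ci_high: float
    exposure_terms: list[str]
    exposure_coefficients: np.ndarray
    base_fit: TobitFit

    def component_shares(self) -> dict[str, dict[str, float]]:
        return component_weights(self)


def fit_qgcomp_tobit(data: pd.DataFrame,
                     quant_specs: Mapping[str, QuantizationSpec],
                     covariates: Sequence[str],
                     outcome: str,
                     censor_flag: str,
                     weights: np.ndarray | None = None,
                     robust: bool | None = None) -> MixtureEstimate:
    """Joint weighted Tobit fit of all quantized components.

    ``quant_specs`` maps each component chemical to its (full-sample)
    quantization; the aggregate total is excluded by construction, since it
    is collinear with the components.
    """
    qs = {s.q for s in quant_specs.values()}
    if len(qs) != 1:
        raise ValueError(f"components quantized with differing q: {sorted(qs)}")
    df = data.copy()
    score_cols = []
    for chem, spec in quant_specs.items():
        col = f"{chem}_score"
        df[col] = score(df[chem].to_numpy(), spec).astype(float)
        score_cols.append(col)
    smat = df[score_cols].to_numpy()
    if np.linalg.matrix_rank(smat - smat.mean(axis=0)) < len(score_cols):
        corr = np.corrcoef(smat, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "quantized exposures are collinear; most correlated pair: "
            f"{score_cols[i]} and {score_cols[j]}")

    spec = ModelSpec(outcome=outcome, terms=score_cols + list(covariates),
                     censor_flag=censor_flag)
    fit = fit_tobit(spec, df, weights=weights, robust=robust)
    idx = [fit.term_names.index(c) for c in score_cols]
    coefs = fit.coefficients[idx]
    psi = float(coefs.sum())
    block = fit.covariance[np.ix_(idx, idx)]
    var = float(np.ones(len(idx)) @ block @ np.ones(len(idx)))
    se = float(np.sqrt(var))
    return MixtureEstimate(
        psi=psi, se=se, ci_low=psi - Z_95 * se, ci_high=psi + Z_95 * se,
        exposure_terms=score_cols, exposure_coefficients=coefs, base_fit=fit)


def bootstrap_psi(data: pd.DataFrame,
                  quant_specs: Mapping[str, QuantizationSpec],
                  covariates: Sequence[str],
                  outcome: str,
                  censor_flag: str,
                  weights: np.ndarray | None = None,
                  n_boot: int = 200,
                  seed: int = 0) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for psi, as a cross-check on the default
    delta-method interval. Resamples rows (with their weights); quantization
    cutpoints stay fixed at the full-sample values, mirroring the analysis."""
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20")
    rng = np.random.default_rng(seed)
    n = len(data)
    w = None if weights is None else np.asarray(weights, dtype=float)
    psis = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        est = fit_qgcomp_tobit(data.iloc[idx].reset_index(drop=True),
                               quant_specs, covariates, outcome, censor_flag,
                               weights=None if w is None else w[idx])
        psis.append(est.psi)
    lo, hi = np.percentile(psis, [2.5, 97.5])
    return float(lo), float(hi)


def component_weights(est: MixtureEstimate) -> dict[str, dict[str, float]]:
    """Signed per-chemical shares: positive-coefficient components share
    the positive partial sum, negatives the negative one."""
    coefs = est.exposure_coefficients
    pos_sum = coefs[coefs > 0].sum()
    neg_sum = coefs[coefs < 0].sum()
    if pos_sum == 0.0 and neg_sum == 0.0:
        return {"positive": {}, "negative": {}, "defined": False}  # type: ignore[dict-item]
    pos, neg = {}, {}
    for name, c in zip(est.exposure_terms, coefs):
        chem = name.removesuffix("_score")
        if c > 0:
            pos[chem] = float(c / pos_sum)
        elif c < 0:
            neg[chem] = float(c / neg_sum)
    return {"positive": pos, "negative": neg, "defined": True}  # type: ignore[dict-item]
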