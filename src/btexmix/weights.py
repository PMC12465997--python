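"""Stabilized inverse-probability-of-censoring weights for medication use.

"Censoring" here means taking glucose-lowering medication. Treatment at the
outcome visit is absorbed by the censored-regression likelihood; treatment
at the *initial* visit censors a covariate (initial HbA1c), which the
outcome model cannot absorb, so models adjusting for initial HbA1c drop
Home-Visit-medicated participants ("artificial censoring") and reweight the
remainder by stabilized inverse probabilities of remaining untreated:

    w = P(untreated | stabilizer covariates) / P(untreated | full covariates)

Both probabilities come from logistic regressions; the stabilizer set is by
default age at the Home Visit and BMI, i.e. variables already in the
analysis models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tobit import build_design

#: denominator model: all covariates in the descriptive table plus age x BMI
DEFAULT_TREATMENT_TERMS = [
    "age_months", "bmi", "age_months:bmi", "C(sex)", "C(race)",
    "C(education)", "C(employment)", "C(smoking)", "C(insurance)",
    "C(prior_btex)", "C(adi_quartile)",
]
DEFAULT_STABILIZER_TERMS = ["age_months", "bmi"]

MED_COLUMN = {"hv": "med_hv", "ce": "med_ce"}


@dataclass
class TreatmentModel:
    """Logistic model of being *untreated* at a visit."""

    visit: str
    terms: list[str]
    coefficients: np.ndarray
    term_names: list[str]
    p_untreated: pd.Series       # indexed like the fitting data
    converged: bool


@dataclass
class CensoringWeights:
    participant_id: pd.Series
    w_hv: pd.Series
    w_ce: pd.Series
    p_hv_num: pd.Series
    p_hv_denom: pd.Series
    p_ce_num: pd.Series
    p_ce_denom: pd.Series
    truncated_fraction: float = 0.0

    def diagnostics(self) -> dict:
        w = self.w_hv * self.w_ce
        return {
            "mean_w_hv": float(self.w_hv.mean()),
            "mean_w_ce": float(self.w_ce.mean()),
            "mean_w_total": float(w.mean()),
            "min_w_total": float(w.min()),
            "max_w_total": float(w.max()),
            "fraction_truncated": self.truncated_fraction,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "w_hv": self.w_hv, "w_ce": self.w_ce,
            "w_total": self.w_hv * self.w_ce,
        })


def fit_treatment_model(data: pd.DataFrame, visit: str,
                        covariate_set: Sequence[str] | None = None,
                        ) -> TreatmentModel:
    """Logistic regression of being untreated at ``visit`` ('hv' or 'ce').

    For the Clinical Exam the model is fit among participants untreated at
    the Home Visit (it models *starting* medication between visits);
    continuing users are handled by the Home-Visit weight.
    """
    if visit not in MED_COLUMN:
        raise ValueError("visit must be 'hv' or 'ce'")
    terms = list(covariate_set) if covariate_set is not None \
        else list(DEFAULT_TREATMENT_TERMS)
    sub = data if visit == "hv" else data[data["med_hv"] == 0]
    y = 1 - sub[MED_COLUMN[visit]].to_numpy(dtype=float)   # 1 = untreated
    if y.min() == y.max():
        raise ValueError(
            f"all rows {'untreated' if y.min() == 1 else 'treated'} at {visit}; "
            "treatment model not identified")
    X, names = build_design(sub, terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        p = np.asarray(res.predict(X))
    if np.any(p < 1e-10) or np.any(p > 1 - 1e-10):
        j = int(np.argmax(np.abs(res.params[1:])) + 1)
        raise ValueError(
            f"apparent separation in treatment model at {visit}; "
            f"largest coefficient on term {names[j]!r}")
    return TreatmentModel(
        visit=visit, terms=terms, coefficients=np.asarray(res.params),
        term_names=names, p_untreated=pd.Series(p, index=sub.index),
        converged=bool(res.converged))


def stabilized_weights(data: pd.DataFrame,
                       denom_terms: Sequence[str] | None = None,
                       num_terms: Sequence[str] | None = None,
                       prob_floor: float = 0.01,
                       truncate_percentiles: tuple[float, float] | None = None,
                       on_floor: str = "truncate") -> CensoringWeights:
    """Build stabilized weights for both visits.

    ``w_hv`` is the ratio of stabilizer-model to full-model probabilities of
    being untreated at the Home Visit, defined for every row. ``w_ce`` is
    the analogous ratio for remaining untreated at the Clinical Exam, fit
    and applied among rows untreated at the Home Visit (1 elsewhere).
    Denominator probabilities below ``prob_floor`` are truncated (default)
    or raised as positivity violations.
    """
    denom_terms = list(denom_terms) if denom_terms is not None \
        else list(DEFAULT_TREATMENT_TERMS)
    num_terms = list(num_terms) if num_terms is not None \
        else list(DEFAULT_STABILIZER_TERMS)

    out = {}
    n_floor = 0
    for visit in ("hv", "ce"):
        denom = fit_treatment_model(data, visit, denom_terms)
        num = fit_treatment_model(data, visit, num_terms)
        p_d = denom.p_untreated.reindex(data.index)
        p_n = num.p_untreated.reindex(data.index)
        low = p_d < prob_floor
        if low.any():
            n_floor += int(low.sum())
            if on_floor == "error":
                raise ValueError(
                    f"{int(low.sum())} denominator probabilities below "
                    f"{prob_floor} at {visit}: positivity violation")
            p_d = p_d.clip(lower=prob_floor)
        w = (p_n / p_d).fillna(1.0)   # rows outside the eligible set -> 1
        out[visit] = (w, p_n.fillna(1.0), p_d.fillna(1.0))

    w_hv, p_hv_n, p_hv_d = out["hv"]
    w_ce, p_ce_n, p_ce_d = out["ce"]
    frac_trunc = 0.0
    if truncate_percentiles is not None:
        lo, hi = truncate_percentiles
        for w in (w_hv, w_ce):
            ql, qh = np.percentile(w, [lo, hi])
            frac_trunc += float(((w < ql) | (w > qh)).mean())
            w.clip(lower=ql, upper=qh, inplace=True)
    frac_trunc += n_floor / max(len(data), 1)
    return CensoringWeights(
        participant_id=data["participant_id"], w_hv=w_hv, w_ce=w_ce,
        p_hv_num=p_hv_n, p_hv_denom=p_hv_d,
        p_ce_num=p_ce_n, p_ce_denom=p_ce_d,
        truncated_fraction=frac_trunc)


def apply_censoring_scheme(data: pd.DataFrame, model: str,
                           weights: CensoringWeights,
                           ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Return (analysis table, per-row weight, outcome-censor flag).

    * ``eq1`` (initial HbA1c): all rows; censor flag = medication at the
      Home Visit; weight = Home-Visit weight.
    * ``eq2`` (final HbA1c, not adjusting for initial): all rows; censor
      flag = medication at the Clinical Exam; weight = HV x CE weights.
    * ``eq3`` (final HbA1c adjusting for initial): Home-Visit-medicated rows
      are removed (their initial HbA1c is a censored covariate); censor flag
      = medication at the Clinical Exam; weight = HV x CE weights.
    """
    if model not in ("eq1", "eq2", "eq3"):
        raise ValueError("model must be 'eq1', 'eq2' or 'eq3'")
    if model == "eq1":
        tab = data
        w = weights.w_hv.reindex(tab.index)
        flag = tab["med_hv"].astype(int)
    elif model == "eq2":
        tab = data
        w = (weights.w_hv * weights.w_ce).reindex(tab.index)
        flag = tab["med_ce"].astype(int)
    else:
        tab = data[data["med_hv"] == 0]
        w = (weights.w_hv * weights.w_ce).reindex(tab.index)
        flag = tab["med_ce"].astype(int)
    if w.isna().any():
        raise ValueError(f"weights undefined for {int(w.isna().sum())} rows "
                         f"of the {model} analysis table")
    return tab, w, flag
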