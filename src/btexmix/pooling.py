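"""Chained-equations multiple imputation of covariates and Rubin's-rules
pooling of censored-regression estimates.

Only covariates are ever imputed; exposures, outcomes, durations and
medication flags are required complete and participate as predictors in
every imputation model (the usual congeniality guidance). Continuous
covariates are imputed by predictive-mean matching (nearest-prediction
donor pool, default 5 donors); binary and categorical covariates by
multinomial logistic draws. Chains are seeded per imputation so runs are
exactly reproducible.

Pooling follows Rubin's rules with Barnard-Rubin small-sample degrees of
freedom: for m estimates q_i with within variances u_i,

    qbar = mean(q_i),  ubar = mean(u_i),  b = var(q_i),
    t = ubar + (1 + 1/m) b,
    CI = qbar +/- t_{df} sqrt(t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .config import CATEGORY_LEVELS, CHEMICALS, NEVER_MISSING, TOTAL, PoolingConfig
from .quantize import QuantizationSpec, fit_cutpoints, score, indicators
from .tobit import ModelSpec, contrasts, fit_tobit
from .qgcomp import fit_qgcomp_tobit
from .weights import apply_censoring_scheme, stabilized_weights

#: adjustment set Z of the analysis models (full-sample analyses)
DEFAULT_Z_TERMS = [
    "age_months", "C(sex)", "C(race)", "C(education)", "C(employment)",
    "C(smoking)", "C(insurance)", "bmi", "C(prior_btex)", "C(adi_quartile)",
]

MODEL_TERMS = {
    "eq1": ["duration1"],
    "eq2": ["duration1", "duration2"],
    "eq3": ["hba1c_initial", "duration1", "hba1c_initial:duration1", "duration2"],
}
MODEL_OUTCOME = {"eq1": "hba1c_initial", "eq2": "hba1c_final", "eq3": "hba1c_final"}


# ----------------------------------------------------------------------
# imputation

def _predictor_matrix(df: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric predictor matrix from all variables except ``exclude``."""
    cols = []
    for col in df.columns:
        if col in (exclude, "participant_id", "latent_initial", "latent_final"):
            continue
        if col in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[col]
            for lev in levels[1:]:
                cols.append((df[col] == lev).to_numpy(dtype=float))
        else:
            x = df[col].to_numpy(dtype=float)
            if col in CHEMICALS or col == TOTAL:
                x = np.log(np.clip(x, 1e-6, None))
            cols.append(x)
    return np.column_stack(cols)


def impute(data: pd.DataFrame, config: PoolingConfig) -> list[pd.DataFrame]:
    """Chained-equations imputation returning ``m_imputations`` completed
    tables. Observed values are never altered."""
    config.validate()
    miss_cols = [c for c in data.columns if data[c].isna().any()]
    bad = [c for c in miss_cols if c in NEVER_MISSING]
    if bad:
        raise ValueError(
            f"missing values in non-imputable columns {bad}: only covariates "
            "may be imputed")
    for c in miss_cols:
        frac = data[c].isna().mean()
        if frac > 0.5:
            raise ValueError(f"{c!r} is {frac:.0%} missing; refusing to impute")
    if not miss_cols:
        return [data.copy() for _ in range(config.m_imputations)]

    completed = []
    for m in range(config.m_imputations):
        rng = np.random.default_rng(config.seed + m)
        df = data.copy()
        # initialize missing entries with random observed donors
        for col in miss_cols:
            obs = df[col].dropna().to_numpy()
            nmiss = int(df[col].isna().sum())
            df.loc[df[col].isna(), col] = rng.choice(obs, size=nmiss)
        for _ in range(config.chain_iterations):
            for col in miss_cols:
                mask = data[col].isna().to_numpy()
                X = _predictor_matrix(df, exclude=col)
                Xo, Xm = X[~mask], X[mask]
                if col in CATEGORY_LEVELS:
                    y = data.loc[~mask, col].astype(str).to_numpy()
                    if np.unique(y).size < 2:
                        df.loc[mask, col] = y[0]
                        continue
                    # standardize for optimizer conditioning (affine
                    # reparameterization; fitted probabilities unchanged)
                    mu, sd = Xo.mean(axis=0), Xo.std(axis=0)
                    sd[sd == 0] = 1.0
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        clf = LogisticRegression(max_iter=200, C=1e4, tol=1e-3)
                        clf.fit((Xo - mu) / sd, y)
                        probs = clf.predict_proba((Xm - mu) / sd)
                    cum = probs.cumsum(axis=1)
                    draws = rng.uniform(size=(len(Xm), 1))
                    pick = (draws > cum).sum(axis=1)
                    df.loc[mask, col] = clf.classes_[pick]
                else:
                    yo = data.loc[~mask, col].to_numpy(dtype=float)
                    XtX = Xo.T @ Xo + 1e-8 * np.eye(Xo.shape[1])
                    beta = np.linalg.solve(XtX, Xo.T @ yo)
                    pred_o, pred_m = Xo @ beta, Xm @ beta
                    # predictive-mean matching: draw among nearest donors
                    order = np.argsort(pred_o)
                    pos = np.searchsorted(pred_o[order], pred_m)
                    vals = np.empty(len(pred_m))
                    k = config.pmm_donors
                    for i, p in enumerate(pos):
                        lo = max(0, p - k)
                        hi = min(len(order), p + k)
                        cand = order[lo:hi]
                        d = np.abs(pred_o[cand] - pred_m[i])
                        donors = cand[np.argsort(d)[:k]]
                        vals[i] = yo[donors[rng.integers(len(donors))]]
                    df.loc[mask, col] = vals
        completed.append(df)
    return completed


# ----------------------------------------------------------------------
# Rubin's rules

@dataclass
class PooledResult:
    term: str
    qbar: float
    ubar: float
    b: float
    t_total: float
    df: float
    ci_low: float
    ci_high: float
    fmi: float
    m: int
    n_used: int = 0
    n_censored: int = 0
    unstable: bool = False


def pool(estimates: Sequence[float], variances: Sequence[float],
         df_com: float, term: str = "", m: int | None = None) -> PooledResult:
    """Rubin's rules with Barnard-Rubin degrees of freedom."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.size < 2:
        raise ValueError("need at least 2 imputation estimates to pool")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(u))):
        raise ValueError("non-finite estimates or variances")
    m = q.size if m is None else m
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    t = ubar + (1 + 1 / m) * b
    if b > 0:
        lam = (1 + 1 / m) * b / t
        df_old = (m - 1) / lam**2
        df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        r = (1 + 1 / m) * b / ubar
        fmi = (r + 2 / (df + 3)) / (r + 1)
    else:
        df = df_com
        fmi = 0.0
    half = float(sps.t.ppf(0.975, df)) * np.sqrt(t)
    return PooledResult(term=term, qbar=qbar, ubar=ubar, b=b, t_total=float(t),
                        df=float(df), ci_low=qbar - half, ci_high=qbar + half,
                        fmi=float(fmi), m=m)


# ----------------------------------------------------------------------
# end-to-end pooled analysis

def bmi_class(df: pd.DataFrame) -> pd.Series:
    """Underweight/normal (<25), overweight (25-29.9), obese (>=30)."""
    b = df["bmi"].astype(float)
    return pd.Series(np.select([b < 25, b < 30], ["<25", "25-30"], ">=30"),
                     index=df.index)

_STRATUM_DROP = {"bmi_class": "bmi", "adi_quartile": "C(adi_quartile)",
                 "race": "C(race)"}


def fit_cutpoints_all(data: pd.DataFrame, q: int = 4
                      ) -> dict[str, QuantizationSpec]:
    """Full-sample quartile cutpoints for the four chemicals and the total."""
    return {chem: fit_cutpoints(data[chem].to_numpy(), q=q, chemical=chem)
            for chem in list(CHEMICALS) + [TOTAL]}


def run_pooled_analysis(data: pd.DataFrame, model: str, exposure: str,
                        config: PoolingConfig,
                        stratum: tuple[str, str] | None = None,
                        z_terms: Sequence[str] | None = None,
                        denom_terms: Sequence[str] | None = None,
                        num_terms: Sequence[str] | None = None,
                        quant_specs: Mapping[str, QuantizationSpec] | None = None,
                        ) -> list[PooledResult]:
    """Impute, weight, fit and pool one (model, exposure, stratum) cell.

    ``exposure`` is a chemical name, ``total_btex``, or ``"mixture"``.
    ``stratum`` is None or ``(variable, level)`` with variable one of
    ``bmi_class``, ``adi_quartile``, ``race``; cutpoints always come from
    the full sample. Non-converged fits are dropped from pooling with a
    warning; more than 20% dropped is an error.
    """
    if model not in MODEL_TERMS:
        raise ValueError("model must be 'eq1', 'eq2' or 'eq3'")
    specs = quant_specs if quant_specs is not None else fit_cutpoints_all(data)
    z = list(z_terms) if z_terms is not None else list(DEFAULT_Z_TERMS)
    if stratum is not None:
        var, _ = stratum
        if var not in _STRATUM_DROP:
            raise ValueError(f"unknown stratification variable {var!r}")
        z = [t for t in z if t != _STRATUM_DROP[var]]

    per_term: dict[str, list[tuple[float, float]]] = {}
    meta = {"n_used": 0, "n_censored": 0, "df_com": 1.0, "unstable": False}
    n_failed = 0
    completed = impute(data, config)
    for imp in completed:
        w_all = stabilized_weights(imp, denom_terms=denom_terms,
                                   num_terms=num_terms)
        tab, w, flag = apply_censoring_scheme(imp, model, w_all)
        tab = tab.copy()
        tab["_censor"] = flag
        tab["_w"] = w
        if stratum is not None:
            var, level = stratum
            labels = bmi_class(tab) if var == "bmi_class" else tab[var]
            tab = tab[labels == level]
            if len(tab) < 50:
                meta["unstable"] = True
        try:
            if exposure == "mixture":
                est = fit_qgcomp_tobit(
                    tab, {c: specs[c] for c in CHEMICALS}, covariates=(
                        MODEL_TERMS[model] + z),
                    outcome=MODEL_OUTCOME[model], censor_flag="_censor",
                    weights=tab["_w"].to_numpy())
                fit = est.base_fit
                if not fit.converged:
                    n_failed += 1
                    continue
                per_term.setdefault("psi", []).append((est.psi, est.se**2))
            else:
                sc = score(tab[exposure].to_numpy(), specs[exposure])
                ind = indicators(sc, q=specs[exposure].q)
                qnames = [f"{exposure}_q{j}" for j in range(2, specs[exposure].q + 1)]
                for j, name in enumerate(qnames):
                    tab[name] = ind[:, j].astype(float)
                mspec = ModelSpec(outcome=MODEL_OUTCOME[model],
                                  terms=qnames + MODEL_TERMS[model] + z,
                                  censor_flag="_censor")
                fit = fit_tobit(mspec, tab, weights=tab["_w"].to_numpy())
                if not fit.converged:
                    n_failed += 1
                    continue
                for c in contrasts(fit, qnames):
                    per_term.setdefault(c.term, []).append((c.estimate, c.se**2))
            meta["n_used"] = fit.n_used
            meta["n_censored"] = fit.n_censored
            meta["df_com"] = max(fit.n_used - len(fit.term_names) - 1, 1)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
    if n_failed:
        warnings.warn(f"{n_failed} of {len(completed)} imputation fits "
                      "excluded (non-convergence)")
    if n_failed > 0.2 * len(completed):
        raise RuntimeError(
            f"{n_failed}/{len(completed)} imputation fits failed; pooled "
            "result would be unreliable")

    results = []
    for term, pairs in per_term.items():
        est, var = zip(*pairs)
        pr = pool(est, var, df_com=meta["df_com"], term=term,
                  m=config.m_imputations)
        pr.n_used = meta["n_used"]
        pr.n_censored = meta["n_censored"]
        pr.unstable = meta["unstable"]
        results.append(pr)
    return results
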