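"""Weighted Tobit (censored-normal) regression with observation-specific
right censoring.

The latent outcome is the *untreated* biomarker value. For participants on
glucose-lowering medication the observed value is a lower bound: the latent
value is as high or higher. Each censored row therefore contributes an
upper-tail (survival) probability to the likelihood, at its own observed
value, instead of a density term:

    l_i = w_i * [ log phi((y_i - x_i b)/s) - log s ]        (uncensored)
    l_i = w_i * log Phi-bar((y_i - x_i b)/s)                (censored)

This differs from the classical fixed-threshold Tobit: the censoring point
varies by observation. The scale is parameterized as log(sigma) for
unconstrained quasi-Newton optimization; starting values come from weighted
least squares on the uncensored rows, so fits are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_ndtr

from .config import CATEGORY_LEVELS

Z_95 = 1.959963984540054


# ----------------------------------------------------------------------
# design-matrix mini-language

def expand_term(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """One term -> columns. Supported forms: numeric column name,
    ``C(col)`` categorical dummy expansion (first canonical level is the
    reference), and ``a:b`` product of two numeric columns."""
    if term.startswith("C(") and term.endswith(")"):
        col = term[2:-1]
        levels = CATEGORY_LEVELS.get(col)
        if levels is None:
            vals = sorted(pd.unique(df[col].dropna()))
        else:
            vals = [l for l in levels if l in set(df[col].dropna())]
        cols = [(df[col] == lev).to_numpy(dtype=float) for lev in vals[1:]]
        names = [f"{col}[{lev}]" for lev in vals[1:]]
        if not cols:
            return np.empty((len(df), 0)), []
        return np.column_stack(cols), names
    if ":" in term:
        a, b = term.split(":", 1)
        x = df[a].to_numpy(dtype=float) * df[b].to_numpy(dtype=float)
        return x[:, None], [term]
    return df[term].to_numpy(dtype=float)[:, None], [term]


def build_design(df: pd.DataFrame, terms: Sequence[str],
                 add_intercept: bool = True) -> tuple[np.ndarray, list[str]]:
    blocks, names = [], []
    if add_intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("Intercept")
    for t in terms:
        x, nm = expand_term(df, t)
        blocks.append(x)
        names.extend(nm)
    return np.column_stack(blocks), names


@dataclass
class ModelSpec:
    """Outcome, design terms, censoring flag and optional weight column."""

    outcome: str
    terms: list[str]
    censor_flag: str
    weight_column: str | None = None


def parse_formula(formula: str, censor_flag: str,
                  weight_column: str | None = None) -> ModelSpec:
    """Build a ModelSpec from ``"outcome ~ term + term + ..."``.

    Terms use the same mini-language as ``build_design``: numeric columns,
    ``C(col)`` categorical expansions and ``a:b`` numeric products. The
    intercept is always implicit.
    """
    if formula.count("~") != 1:
        raise ValueError(f"formula must contain exactly one '~': {formula!r}")
    lhs, rhs = (side.strip() for side in formula.split("~"))
    if not lhs:
        raise ValueError("formula has no outcome")
    terms = [t.strip() for t in rhs.split("+") if t.strip()] if rhs else []
    return ModelSpec(outcome=lhs, terms=terms, censor_flag=censor_flag,
                     weight_column=weight_column)


@dataclass
class TobitFit:
    """MLE result for one weighted censored-normal regression."""

    term_names: list[str]
    coefficients: np.ndarray          # betas, in term order
    log_sigma: float
    cov_model: np.ndarray             # inverse negative Hessian, (p+1)x(p+1)
    cov_robust: np.ndarray            # sandwich
    loglik: float
    n_used: int
    n_censored: int
    n_dropped: int
    converged: bool
    gradient_norm: float
    default_robust: bool              # which covariance contrasts() uses

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def covariance(self) -> np.ndarray:
        return self.cov_robust if self.default_robust else self.cov_model

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.term_names.index(name)])

    def to_json(self) -> str:
        return json.dumps({
            "terms": self.term_names,
            "coefficients": self.coefficients.tolist(),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "se_model": np.sqrt(np.diag(self.cov_model)[:-1]).tolist(),
            "se_robust": np.sqrt(np.diag(self.cov_robust)[:-1]).tolist(),
            "n_used": self.n_used, "n_censored": self.n_censored,
            "converged": self.converged, "gradient_norm": self.gradient_norm,
        })


def _prepare(spec: ModelSpec, data: pd.DataFrame,
             weights: np.ndarray | None):
    df = data
    y_all = df[spec.outcome].to_numpy(dtype=float)
    keep = np.isfinite(y_all)
    X_all, names = build_design(df, spec.terms)
    keep &= np.all(np.isfinite(X_all), axis=1)
    n_dropped = int((~keep).sum())
    y, X = y_all[keep], X_all[keep]
    cens = df[spec.censor_flag].to_numpy(dtype=float)[keep].astype(bool)
    if weights is None:
        if spec.weight_column is not None:
            w = df[spec.weight_column].to_numpy(dtype=float)[keep]
        else:
            w = np.ones(keep.sum())
    else:
        w = np.asarray(weights, dtype=float)[keep]
    if np.any(w < 0):
        raise ValueError("negative weights")
    if not np.all(np.isfinite(X)):
        bad = np.where(~np.all(np.isfinite(X_all), axis=1))[0]
        raise ValueError(f"non-finite design entries in rows {bad[:10].tolist()}")
    return y, X, cens, w, names, n_dropped


def tobit_loglik(params: np.ndarray, y: np.ndarray, X: np.ndarray,
                 censored: np.ndarray, weights: np.ndarray) -> float:
    """Weighted log-likelihood at ``params = (beta, log_sigma)``."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    z = (y - X @ beta) / sigma
    ll = np.where(censored,
                  log_ndtr(-z),                                   # P(latent >= y)
                  -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - log_sigma)
    return float(np.sum(weights * ll))


def _score_rows(params, y, X, censored, weights):
    """Per-row gradient of the weighted loglik w.r.t. (beta, log_sigma)."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    z = (y - X @ beta) / sigma
    # hazard of the standard normal at z: phi(z)/Phi-bar(z)
    haz = np.exp(stats.norm.logpdf(z) - log_ndtr(-z))
    dmu = np.where(censored, haz, z) / sigma          # d l / d (x b)
    dls = np.where(censored, haz * z, z**2 - 1.0)     # d l / d log sigma
    g = np.column_stack([X * dmu[:, None], dls])
    return g * weights[:, None]


def _hessian(params, y, X, censored, weights):
    """Analytic Hessian of the weighted loglik w.r.t. (beta, log_sigma).

    With z = (y - x b)/sigma and normal hazard h(z) = phi(z)/Phi-bar(z)
    (so h' = h (h - z)), the per-row second derivatives in (x b, log sigma)
    are -1/sigma^2, -2z/sigma, -2z^2 for uncensored rows and -h'/sigma^2,
    -(z h' + h)/sigma, -(z^2 h' + z h) for censored rows.
    """
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    z = (y - X @ beta) / sigma
    haz = np.exp(stats.norm.logpdf(z) - log_ndtr(-z))
    hprime = haz * (haz - z)
    a = np.where(censored, -hprime, -1.0) / sigma**2
    b = np.where(censored, -(z * hprime + haz), -2.0 * z) / sigma
    c = np.where(censored, -(z**2 * hprime + z * haz), -2.0 * z**2)
    wa, wb = weights * a, weights * b
    p = X.shape[1]
    H = np.empty((p + 1, p + 1))
    H[:p, :p] = X.T @ (X * wa[:, None])
    H[:p, p] = H[p, :p] = X.T @ wb
    H[p, p] = np.sum(weights * c)
    return H


def fit_tobit(spec: ModelSpec, data: pd.DataFrame,
              weights: np.ndarray | None = None,
              robust: bool | None = None) -> TobitFit:
    """Maximize the censored-normal likelihood by quasi-Newton iteration.

    Starting values are WLS on the uncensored rows. The model-based
    covariance is the inverse negative Hessian (analytic); the robust
    covariance is the usual sandwich over per-row scores. ``contrasts``
    uses the sandwich by default whenever non-unit weights are present
    (the weighted likelihood is a pseudo-likelihood).
    """
    y, X, cens, w, names, n_dropped = _prepare(spec, data, weights)
    if y.size == 0:
        raise ValueError("no usable rows")
    if cens.all():
        raise ValueError("all rows censored: latent scale not identified")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank deficient ({rank} < {X.shape[1]}); "
            f"terms: {names}")

    # deterministic start: WLS on uncensored rows
    Xu, yu, wu = X[~cens], y[~cens], w[~cens]
    WX = Xu * wu[:, None]
    beta0, *_ = np.linalg.lstsq(WX.T @ Xu, WX.T @ yu, rcond=None)
    resid = yu - Xu @ beta0
    s0 = np.sqrt(np.average(resid**2, weights=wu)) if yu.size > 1 else 1.0
    x0 = np.append(beta0, np.log(max(s0, 1e-3)))

    def neg(params):
        return -tobit_loglik(params, y, X, cens, w)

    def grad(params):
        return -_score_rows(params, y, X, cens, w).sum(axis=0)

    res = optimize.minimize(neg, x0, jac=grad, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 1000})
    # polish with Newton steps off the analytic Hessian if needed
    params = res.x
    gnorm = float(np.linalg.norm(grad(params), ord=np.inf))
    if gnorm > 1e-6:
        for _ in range(20):
            H = -_hessian(params, y, X, cens, w)
            try:
                step = np.linalg.solve(H, grad(params))
            except np.linalg.LinAlgError:
                break
            new = params - step
            if not np.isfinite(neg(new)) or neg(new) > neg(params) + 1e-12:
                break
            params = new
            gnorm = float(np.linalg.norm(grad(params), ord=np.inf))
            if gnorm <= 1e-6:
                break
    converged = gnorm <= 1e-6

    H = -_hessian(params, y, X, cens, w)  # Hessian of the NEGATIVE loglik
    try:
        cov_model = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_model = np.linalg.pinv(H)
    cov_model = 0.5 * (cov_model + cov_model.T)
    G = _score_rows(params, y, X, cens, w)
    meat = G.T @ G
    cov_robust = cov_model @ meat @ cov_model
    cov_robust = 0.5 * (cov_robust + cov_robust.T)

    if robust is None:
        robust = not np.allclose(w, 1.0)
    return TobitFit(
        term_names=names,
        coefficients=params[:-1],
        log_sigma=float(params[-1]),
        cov_model=cov_model,
        cov_robust=cov_robust,
        loglik=float(-neg(params)),
        n_used=int(y.size),
        n_censored=int(cens.sum()),
        n_dropped=n_dropped,
        converged=bool(converged),
        gradient_norm=gnorm,
        default_robust=bool(robust),
    )


@dataclass
class Contrast:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float


def contrasts(fit: TobitFit, terms: Sequence[str],
              robust: bool | None = None) -> list[Contrast]:
    """Wald estimates and 95% CIs for the named coefficients."""
    cov = fit.cov_robust if (robust if robust is not None
                             else fit.default_robust) else fit.cov_model
    out = []
    for t in terms:
        if t not in fit.term_names:
            raise KeyError(f"term {t!r} not in fit ({fit.term_names})")
        i = fit.term_names.index(t)
        est = float(fit.coefficients[i])
        se = float(np.sqrt(cov[i, i]))
        out.append(Contrast(t, est, se, est - Z_95 * se, est + Z_95 * se))
    return out
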