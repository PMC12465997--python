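"""Censored-normal regression: likelihood oracles, fitting, covariance."""

import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest

from btexmix.tobit import (ModelSpec, build_design, contrasts, fit_tobit,
                           parse_formula, tobit_loglik)

from conftest import grid_search_tobit


def normal_sf(z):
    """Upper-tail probability via erfc, independent of scipy."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


class TestLoglik:
    def test_closed_form_uncensored(self):
        # y={1,2,3}, mu=2, sigma^2=2/3: loglik = -3/2 log(2 pi 2/3) - 3/2
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        cens = np.zeros(3, dtype=bool)
        w = np.ones(3)
        sigma = math.sqrt(2.0 / 3.0)
        got = tobit_loglik(np.array([2.0, math.log(sigma)]), y, X, cens, w)
        expected = -1.5 * math.log(2 * math.pi * 2.0 / 3.0) - 1.5
        assert got == pytest.approx(expected, abs=1e-12)

    def test_censored_rows_use_survival_term(self):
        # all three censored at their observed values, mu=2, sigma=1
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        cens = np.ones(3, dtype=bool)
        w = np.ones(3)
        got = tobit_loglik(np.array([2.0, 0.0]), y, X, cens, w)
        expected = sum(math.log(normal_sf(v - 2.0)) for v in y)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_weight_doubling_doubles_loglik(self, tiny_mixed):
        y = tiny_mixed["y"].to_numpy()
        X = np.ones((len(y), 1))
        cens = tiny_mixed["cens"].to_numpy().astype(bool)
        p = np.array([2.1, math.log(0.9)])
        base = tobit_loglik(p, y, X, cens, np.ones(len(y)))
        doubled = tobit_loglik(p, y, X, cens, 2.0 * np.ones(len(y)))
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_permutation_invariance(self, tiny_mixed):
        y = tiny_mixed["y"].to_numpy()
        X = np.ones((len(y), 1))
        cens = tiny_mixed["cens"].to_numpy().astype(bool)
        w = np.linspace(0.5, 1.5, len(y))
        p = np.array([2.4, math.log(1.1)])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        assert tobit_loglik(p, y, X, cens, w) == pytest.approx(
            tobit_loglik(p, y[perm], X[perm], cens[perm], w[perm]), rel=1e-12)

    def test_censored_contribution_nondecreasing_in_mu(self):
        y = np.array([3.0])
        X = np.ones((1, 1))
        cens = np.ones(1, dtype=bool)
        w = np.ones(1)
        mus = np.linspace(-2, 8, 50)
        vals = [tobit_loglik(np.array([m, 0.0]), y, X, cens, w) for m in mus]
        assert np.all(np.diff(vals) > 0)


class TestFit:
    def test_wls_equivalence_no_censoring(self):
        rng = np.random.default_rng(7)
        n = 200
        df = pd.DataFrame({
            "x": rng.normal(size=n),
            "z": rng.normal(size=n),
        })
        df["y"] = 2.0 + 3.0 * df["x"] - 0.5 * df["z"] + 0.4 * rng.normal(size=n)
        df["cens"] = 0.0
        w = rng.uniform(0.5, 2.0, size=n)
        fit = fit_tobit(ModelSpec("y", ["x", "z"], "cens"), df, weights=w)
        X = np.column_stack([np.ones(n), df["x"], df["z"]])
        WX = X * w[:, None]
        beta = np.linalg.solve(WX.T @ X, WX.T @ df["y"].to_numpy())
        assert np.allclose(fit.coefficients, beta, atol=1e-6)
        assert fit.n_censored == 0
        assert fit.converged

    def test_grid_search_oracle_three_rows(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "cens": [0.0, 0.0, 1.0]})
        fit = fit_tobit(ModelSpec("y", [], "cens"), df)
        mu, sigma = grid_search_tobit(
            df["y"].to_numpy(), np.ones((3, 1)),
            df["cens"].to_numpy().astype(bool), np.ones(3),
            mu_range=(0.0, 6.0), sigma_range=(1e-3, 4.0))
        assert fit.coefficients[0] == pytest.approx(mu, abs=1e-3)
        assert fit.sigma == pytest.approx(sigma, abs=1e-3)

    def test_grid_search_oracle_ten_rows_weighted(self, tiny_mixed):
        w = np.array([1.0, 2.0, 1.0, 1.0, 0.5, 1.5, 1.0, 1.0, 2.0, 0.5])
        fit = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed, weights=w)
        mu, sigma = grid_search_tobit(
            tiny_mixed["y"].to_numpy(), np.ones((10, 1)),
            tiny_mixed["cens"].to_numpy().astype(bool), w,
            mu_range=(0.0, 6.0), sigma_range=(1e-3, 4.0))
        assert fit.coefficients[0] == pytest.approx(mu, abs=1e-3)
        assert fit.sigma == pytest.approx(sigma, abs=1e-3)

    def test_se_matches_finite_difference_hessian(self, tiny_mixed):
        from statsmodels.tools.numdiff import approx_hess
        fit = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed)
        y = tiny_mixed["y"].to_numpy()
        X = np.ones((10, 1))
        cens = tiny_mixed["cens"].to_numpy().astype(bool)
        w = np.ones(10)
        params = np.append(fit.coefficients, fit.log_sigma)
        H = approx_hess(params, lambda p: -tobit_loglik(p, y, X, cens, w))
        cov = np.linalg.inv(H)
        assert np.allclose(fit.cov_model, cov, rtol=1e-4, atol=1e-6)

    def test_all_censored_errors(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "cens": [1.0, 1.0]})
        with pytest.raises(ValueError, match="censored"):
            fit_tobit(ModelSpec("y", [], "cens"), df)

    def test_rank_deficient_design_errors(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0],
                           "x": [1.0, 2.0, 3.0, 4.0],
                           "cens": [0.0] * 4})
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(ValueError, match="rank"):
            fit_tobit(ModelSpec("y", ["x", "x2"], "cens"), df)

    def test_negative_weights_error(self, tiny_mixed):
        w = np.ones(10)
        w[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed, weights=w)

    def test_missing_outcome_rows_dropped_with_count(self, tiny_mixed):
        df = tiny_mixed.copy()
        df.loc[0, "y"] = np.nan
        fit = fit_tobit(ModelSpec("y", [], "cens"), df)
        assert fit.n_dropped == 1
        assert fit.n_used == 9

    def test_default_covariance_robust_iff_nonunit_weights(self, tiny_mixed):
        fit_unit = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed)
        assert not fit_unit.default_robust
        fit_w = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed,
                          weights=np.linspace(0.5, 1.5, 10))
        assert fit_w.default_robust

    def test_covariance_symmetric_psd_and_sigma_positive(self, tiny_mixed):
        fit = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed)
        for cov in (fit.cov_model, fit.cov_robust):
            assert np.allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() > -1e-12
        assert fit.sigma > 0

    def test_json_serialization(self, tiny_mixed):
        fit = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed)
        payload = json.loads(fit.to_json())
        assert payload["terms"] == ["Intercept"]
        assert payload["converged"] is True
        assert payload["n_censored"] == 3


def test_against_r_survreg(tmp_path):
    """Independent oracle: survreg with observation-specific right censoring."""
    rng = np.random.default_rng(21)
    n = 300
    x = rng.normal(size=n)
    latent = 5.0 + 1.5 * x + 0.8 * rng.normal(size=n)
    cens = rng.uniform(size=n) < 0.25
    y = np.where(cens, latent - rng.uniform(0.2, 1.0, size=n), latent)
    df = pd.DataFrame({"y": y, "x": x, "cens": cens.astype(float)})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rcode = f"""
    d <- read.csv("{csv}")
    library(survival)
    f <- survreg(Surv(y, 1 - cens) ~ x, data = d, dist = "gaussian")
    cat(coef(f)[1], coef(f)[2], f$scale, f$loglik[2], sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                         text=True, check=True)
    b0, b1, scale, loglik = map(float, out.stdout.strip().splitlines())
    fit = fit_tobit(ModelSpec("y", ["x"], "cens"), df)
    assert fit.coefficients[0] == pytest.approx(b0, abs=1e-4)
    assert fit.coefficients[1] == pytest.approx(b1, abs=1e-4)
    assert fit.sigma == pytest.approx(scale, abs=1e-4)
    assert fit.loglik == pytest.approx(loglik, abs=1e-3)


class TestContrasts:
    def test_wald_arithmetic(self, tiny_mixed):
        df = tiny_mixed.copy()
        rng = np.random.default_rng(3)
        df["x"] = rng.normal(size=len(df))
        fit = fit_tobit(ModelSpec("y", ["x"], "cens"), df)
        (c,) = contrasts(fit, ["x"])
        i = fit.term_names.index("x")
        se = math.sqrt(fit.cov_model[i, i])
        assert c.se == pytest.approx(se)
        assert c.ci_low == pytest.approx(c.estimate - 1.959963984540054 * se)
        assert c.ci_high == pytest.approx(c.estimate + 1.959963984540054 * se)

    def test_printed_format_example(self):
        # estimate 0.24, SE 0.051 -> CI rounds to (0.14, 0.34)
        est, se = 0.24, 0.051
        lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
        assert (round(lo, 2), round(hi, 2)) == (0.14, 0.34)

    def test_missing_term_errors(self, tiny_mixed):
        fit = fit_tobit(ModelSpec("y", [], "cens"), tiny_mixed)
        with pytest.raises(KeyError):
            contrasts(fit, ["nope"])


class TestDesignAndFormula:
    def test_categorical_expansion_reference_level(self):
        df = pd.DataFrame({"race": ["White", "Black", "Other", "White"]})
        X, names = build_design(df, ["C(race)"])
        assert names == ["Intercept", "race[Black]", "race[Other]"]
        assert X[:, 1].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_interaction_term(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        X, names = build_design(df, ["a:b"])
        assert names == ["Intercept", "a:b"]
        assert X[:, 1].tolist() == [3.0, 8.0]

    def test_parse_formula(self):
        spec = parse_formula(
            "hba1c_final ~ q2 + duration1 + C(race) + hba1c_initial:duration1",
            censor_flag="med_ce")
        assert spec.outcome == "hba1c_final"
        assert spec.terms == ["q2", "duration1", "C(race)",
                              "hba1c_initial:duration1"]
        assert spec.censor_flag == "med_ce"

    def test_parse_formula_errors(self):
        with pytest.raises(ValueError):
            parse_formula("no tilde here", censor_flag="c")
        with pytest.raises(ValueError):
            parse_formula(" ~ x", censor_flag="c")
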