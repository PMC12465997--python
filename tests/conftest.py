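"""Shared fixtures and oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from btexmix import GeneratorConfig, generate_cohort
from btexmix.tobit import tobit_loglik


@pytest.fixture(scope="session")
def cohort_small():
    """A modest generated cohort, shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n_participants=800, seed=11))


@pytest.fixture(scope="session")
def cohort_default():
    """A full-size generated cohort with default settings."""
    return generate_cohort(GeneratorConfig(n_participants=2541, seed=5))


@pytest.fixture
def tiny_mixed():
    """<=20 rows, intercept-only structure, mixed censoring, unit weights."""
    y = np.array([1.0, 2.0, 2.5, 3.0, 3.5, 1.5, 2.2, 4.0, 2.8, 3.2])
    cens = np.array([0, 0, 0, 1, 1, 0, 0, 1, 0, 0], dtype=float)
    return pd.DataFrame({"y": y, "cens": cens})


def grid_search_tobit(y, X, cens, w, mu_range, sigma_range, resolution=1e-3):
    """Coarse-to-fine grid maximization of the intercept-only Tobit
    likelihood, independent of the fitting code path. Returns (mu, sigma)
    at the requested resolution."""
    lo_m, hi_m = mu_range
    lo_s, hi_s = sigma_range
    step = 0.1
    best = None
    while step >= resolution / 2:
        mus = np.arange(lo_m, hi_m + step / 2, step)
        sigmas = np.arange(max(lo_s, step), hi_s + step / 2, step)
        vals = np.empty((mus.size, sigmas.size))
        for i, mu in enumerate(mus):
            for j, s in enumerate(sigmas):
                vals[i, j] = tobit_loglik(
                    np.array([mu, np.log(s)]), y, X, cens, w)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (mus[i], sigmas[j])
        lo_m, hi_m = best[0] - 1.5 * step, best[0] + 1.5 * step
        lo_s, hi_s = max(best[1] - 1.5 * step, resolution), best[1] + 1.5 * step
        step /= 10.0
    return best
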