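"""Configuration objects for the synthetic cohort generator and the pooled analysis.

The generator emulates the statistical structure of an oil-spill cleanup
cohort with two HbA1c measurements: right-skewed, mutually correlated
cumulative BTEX exposures (ppb-days); demographic and anthropometric
covariates; a latent (untreated) HbA1c driven by exposure-quartile effects;
glucose-lowering medication whose use rises with latent HbA1c and lowers the
*observed* HbA1c; and sparse covariate missingness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

CHEMICALS = ("benzene", "toluene", "ethylbenzene", "xylenes")
TOTAL = "total_btex"

#: Target quantiles of cumulative exposure in ppb-days:
#: (min, Q1, median, Q3, 99th percentile, max).
DEFAULT_EXPOSURE_MARGINALS: dict[str, tuple[float, ...]] = {
    "benzene": (0.04, 150.75, 498.76, 1257.73, 5725.05, 10591.67),
    "toluene": (0.24, 574.96, 2106.54, 4828.88, 17361.21, 29656.55),
    "ethylbenzene": (0.02, 122.62, 364.58, 876.62, 3287.96, 4596.40),
    "xylenes": (2.35, 1065.12, 2466.10, 4970.30, 14917.00, 19918.85),
}

#: Canonical category levels; the first level is the modelling reference.
CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "race": ("White", "Black", "Other"),
    "education": ("less_than_hs", "hs_ged", "some_college", "college_plus"),
    "employment": ("working", "unemployed", "other"),
    "smoking": ("never", "former", "light", "heavy"),
    "insurance": ("no", "yes"),
    "prior_btex": ("no", "yes"),
    "adi_quartile": ("Q1/2", "Q3", "Q4"),
}

#: Marginal covariate distributions of the analysis sample (age in years
#: here for readability; the cohort table stores age in months).
DEFAULT_COVARIATE_MARGINALS: dict[str, Any] = {
    "age_years": {"mean": 45.76, "sd": 12.9, "min": 21.0, "max": 90.0},
    "bmi": {"mean": 30.00, "sd": 6.48, "min": 15.0, "max": 60.0},
    "sex": {"male": 0.779, "female": 0.221},
    "race": {"White": 0.522, "Black": 0.399, "Other": 0.078},
    "education": {
        "less_than_hs": 0.218,
        "hs_ged": 0.339,
        "some_college": 0.307,
        "college_plus": 0.135,
    },
    "employment": {"working": 0.558, "unemployed": 0.295, "other": 0.147},
    "smoking": {"never": 0.438, "former": 0.224, "light": 0.227, "heavy": 0.110},
    "insurance": {"no": 0.503, "yes": 0.497},
    "prior_btex": {"no": 0.379, "yes": 0.621},
    "adi_quartile": {"Q1/2": 0.285, "Q3": 0.351, "Q4": 0.364},
}

#: Effects of covariates on latent HbA1c (% HbA1c per unit / vs reference).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "age_years": 0.012,        # per year
    "bmi": 0.030,              # per kg/m^2
    "sex=female": -0.05,
    "race=Black": 0.35,
    "race=Other": 0.10,
    "education=hs_ged": -0.05,
    "education=some_college": -0.08,
    "education=college_plus": -0.12,
    "employment=unemployed": 0.05,
    "employment=other": 0.08,
    "smoking=former": 0.02,
    "smoking=light": 0.05,
    "smoking=heavy": 0.08,
    "insurance=yes": -0.02,
    "prior_btex=yes": 0.03,
    "adi_quartile=Q3": 0.06,
    "adi_quartile=Q4": 0.10,
}

#: Logistic model for glucose-lowering medication at the Home Visit.
#: Keys are "intercept", "latent" (per % latent HbA1c) and covariate terms
#: using the same naming as DEFAULT_COVARIATE_EFFECTS.
DEFAULT_MED_PROPENSITY_HV: dict[str, float] = {
    "intercept": -13.9,
    "latent": 1.8,
    "age_years": 0.01,
    "bmi": 0.01,
}

#: Logistic model for *starting* medication between visits (applied to
#: participants untreated at the Home Visit, driven by latent final HbA1c).
DEFAULT_MED_PROPENSITY_CE: dict[str, float] = {
    "intercept": -15.2,
    "latent": 1.9,
    "age_years": 0.01,
    "bmi": 0.01,
}

#: Fraction of values masked per covariate, mirroring the sparse observed
#: missingness of the analysis sample (at most ~1.4% in any variable).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "race": 10 / 2541,
    "employment": 16 / 2541,
    "smoking": 34 / 2541,
    "prior_btex": 2 / 2541,
    "bmi": 19 / 2541,
    "adi_quartile": 11 / 2541,
    "insurance": 35 / 2541,
}

MISSINGNESS_CAP = 0.05
#: Columns that may never be masked: exposures, outcomes, medication flags,
#: durations and generator truth columns.
NEVER_MISSING = (
    CHEMICALS
    + (TOTAL, "hba1c_initial", "hba1c_final", "latent_initial", "latent_final",
       "med_hv", "med_ce", "duration1", "duration2", "participant_id")
)


def _default_correlation() -> np.ndarray:
    # Near-comonotone components: the published quartiles of the aggregate
    # total almost equal the sums of the component quartiles, which is only
    # possible when the four exposures are very strongly rank-correlated
    # (they all derive from the same total-hydrocarbon measurements).
    r = np.full((4, 4), 0.95)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class GeneratorConfig:
    """Everything the synthetic cohort generator needs, with defaults
    calibrated to the analysis sample's published marginals."""

    n_participants: int = 2541
    seed: int = 0
    exposure_marginals: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_MARGINALS))
    #: Pairwise rank correlation of the four chemicals' cumulative exposures.
    exposure_correlation: np.ndarray = field(default_factory=_default_correlation)
    #: Latent-HbA1c shifts (%) for Q2/Q3/Q4 vs Q1, per chemical, applied to
    #: the *final* measurement; quartiles are taken within the generated
    #: sample. Default: inverted-U on total BTEX.
    quartile_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {TOTAL: (0.24, 0.13, 0.00)})
    #: Same, applied to latent *initial* HbA1c (default none).
    initial_quartile_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict)
    #: Linear per-quartile-score slopes (%, per one-quartile increase),
    #: applied to latent final HbA1c; used for additive-mixture scenarios.
    score_effects: Mapping[str, float] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    covariate_marginals: Mapping[str, Any] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS))
    #: Baseline latent HbA1c (%) at covariate reference / Q1 exposure.
    baseline_initial: float = 4.0
    baseline_final: float = 4.0
    #: Secular drift in latent HbA1c (% per month) applied via durations.
    duration1_effect: float = 0.002
    duration2_effect: float = 0.002
    sigma_hba1c: float = 0.85
    tracking_rho: float = 0.7
    med_propensity_hv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MED_PROPENSITY_HV))
    med_propensity_ce: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MED_PROPENSITY_CE))
    #: Medication-induced lowering of observed HbA1c (%): lognormal, capped
    #: so the observed value never drops below ``med_floor``.
    med_reduction_median: float = 0.8
    med_reduction_log_sd: float = 0.5
    med_floor: float = 4.0
    duration1_dist: tuple[float, float] = (20.0, 6.0)   # months, mean/SD
    duration2_dist: tuple[float, float] = (37.0, 7.7)   # months, mean/SD
    missingness_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    missingness_mechanism: str = "mcar"  # "mcar" | "mar"
    #: Optional loadings of standardized covariates on the exposures' copula
    #: score, inducing exposure-covariate confounding, e.g. {"bmi": 0.3}.
    confounder_strength: Mapping[str, float] = field(default_factory=dict)
    #: Drop latent truth columns (real-data emulation).
    real_data_mode: bool = False

    def validate(self) -> None:
        corr = np.asarray(self.exposure_correlation, dtype=float)
        if corr.shape != (4, 4):
            raise ValueError("exposure_correlation must be 4x4")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("exposure_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("exposure_correlation must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin < -1e-10:
            raise ValueError(
                "exposure_correlation is not positive semi-definite: "
                f"smallest eigenvalue {eigmin:.6g} < 0")
        for col, rate in self.missingness_rate.items():
            if col in NEVER_MISSING:
                raise ValueError(
                    f"missingness may not be injected into {col!r}: exposures, "
                    "outcomes and medication flags are always complete")
            if not 0.0 <= rate <= MISSINGNESS_CAP:
                raise ValueError(
                    f"missingness_rate[{col!r}]={rate} outside [0, {MISSINGNESS_CAP}]")
        for chem, marg in self.exposure_marginals.items():
            if len(marg) != 6:
                raise ValueError(f"{chem}: need 6 quantile anchors, got {len(marg)}")
            if not all(np.diff(marg) >= 0):
                raise ValueError(f"{chem}: quantile anchors must be nondecreasing")
            if marg[0] <= 0:
                raise ValueError(f"{chem}: exposures must be strictly positive")
        if not -1.0 < self.tracking_rho < 1.0:
            raise ValueError("tracking_rho must be in (-1, 1)")
        if self.sigma_hba1c <= 0:
            raise ValueError("sigma_hba1c must be positive")
        if self.missingness_mechanism not in ("mcar", "mar"):
            raise ValueError("missingness_mechanism must be 'mcar' or 'mar'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposure_correlation"] = np.asarray(self.exposure_correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        if "exposure_correlation" in d:
            d["exposure_correlation"] = np.asarray(d["exposure_correlation"], float)
        for key in ("exposure_marginals", "quartile_effects",
                    "initial_quartile_effects"):
            if key in d and d[key] is not None:
                d[key] = {k: tuple(v) for k, v in dict(d[key]).items()}
        for key in ("duration1_dist", "duration2_dist"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PoolingConfig:
    """Multiple-imputation and pooling settings."""

    m_imputations: int = 14
    chain_iterations: int = 5
    seed: int = 0
    #: donors for predictive-mean matching of continuous covariates
    pmm_donors: int = 5

    def validate(self) -> None:
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be >= 2")
        if self.chain_iterations < 1:
            raise ValueError("chain_iterations must be >= 1")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be >= 1")


def load_yaml_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def dump_yaml_config(obj: Mapping[str, Any], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)
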