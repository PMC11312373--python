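"""Cohort-simulation configuration.

One :class:`CohortConfig` object governs every source of randomness and
every distributional assumption of the synthetic cohort: demographic
margins, biomarker marginals (calibrated to the overall column of the
study's baseline characteristics table), covariate prevalences, diet
component intakes, the proportional-hazards event processes and the
censoring mechanisms.  Identical (config, seed) pairs yield byte-identical
cohorts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from ._exceptions import ConfigError

#: marginal distributions matched to the overall-cohort mean ± SD of the
#: baseline table: CRP is right-skewed (SD > mean), hence log-normal;
#: cell counts are gamma (positive, mildly skewed).  Caps are clinically
#: plausible truncation points.
BIOMARKER_DEFAULTS = {
    "crp": {"dist": "lognormal", "mean": 2.59, "sd": 4.34, "cap": 150.0},
    "wbc": {"dist": "gamma", "mean": 6.88, "sd": 2.03, "cap": 50.0},
    "plt": {"dist": "gamma", "mean": 253.0, "sd": 60.0, "cap": 1000.0},
    "neut": {"dist": "gamma", "mean": 4.22, "sd": 1.41, "cap": 30.0},
    "lymph": {"dist": "gamma", "mean": 1.96, "sd": 1.13, "cap": 20.0},
}

#: how strongly each marker's Gaussian copula coordinate loads on the
#: shared (lifestyle + common-marker) factor; lymphocytes load negatively
#: so that inflammation raises the neutrophil-to-lymphocyte ratio.
MARKER_LOADINGS = {"crp": 1.0, "wbc": 1.0, "plt": 0.5, "neut": 1.0, "lymph": -0.5}

COVARIATE_PREVALENCE_DEFAULTS = {
    "race_british": 0.88,
    "smoking_current": 0.10,
    "smoking_previous": 0.35,
    "drinking_current": 0.92,
    "hypertension": 0.27,
    "cvd": 0.38,
    "cancer": 0.024,
    "diabetes": 0.065,
    "respiratory": 0.091,
    "mineral_supp": 0.43,
    "vitamin_supp": 0.32,
    "nsaid_use": 0.44,
    "chol_bp_dm_med": 0.17,
}

#: (log-scale mean of the median, log-sd, loading on the lifestyle factor);
#: positive loading = intake rises with the unhealthy-lifestyle factor.
DIET_COMPONENT_DEFAULTS = {
    "red_meat_wk": (math.log(2.6), 0.45, +0.15),
    "veg_tbsp_day": (math.log(4.0), 0.40, -0.15),
    "fruit_serv_day": (math.log(2.9), 0.50, -0.15),
    "fish_wk": (math.log(2.2), 0.60, -0.15),
    "grains_serv_wk": (math.log(6.5), 0.50, -0.10),
    "urinary_na_mmol": (math.log(65.0), 0.35, +0.10),
}

#: quartile log hazard ratios of the two generated event processes;
#: defaults follow the study's adjusted Q2–Q4 estimates.
TRUE_LOG_HRS_DEATH = {"Q1": 0.0, "Q2": math.log(1.12), "Q3": math.log(1.25), "Q4": math.log(1.58)}
TRUE_LOG_HRS_HOSP = {"Q1": 0.0, "Q2": math.log(1.04), "Q3": math.log(1.09), "Q4": math.log(1.19)}

DEATH_CAUSE_WEIGHTS = {
    "I21": 0.09, "I63": 0.05, "C34": 0.12, "C18": 0.08, "C50": 0.05,
    "J44": 0.07, "J18": 0.03, "E11": 0.02, "G30": 0.03, "R99": 0.46,
}


@dataclass
class CohortConfig:
    n_participants: int = 20_000
    seed: int = 0
    prop_male: float = 0.54
    age_mean: float = 57.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 70.0)
    biomarker_params: dict = field(default_factory=lambda: {k: dict(v) for k, v in BIOMARKER_DEFAULTS.items()})
    covariate_prevalences: dict = field(default_factory=lambda: dict(COVARIATE_PREVALENCE_DEFAULTS))
    diet_component_params: dict = field(default_factory=lambda: dict(DIET_COMPONENT_DEFAULTS))
    diet_recall_fraction: float = 0.47
    #: loading of the shared unhealthy-lifestyle factor on marker copula coordinates
    diet_inflammation_loading: float = 0.25
    #: loading of the common between-marker factor (cross-marker correlation)
    cross_marker_loading: float = 0.40
    true_log_hrs: dict = field(default_factory=lambda: dict(TRUE_LOG_HRS_DEATH))
    hosp_log_hrs: dict = field(default_factory=lambda: dict(TRUE_LOG_HRS_HOSP))
    covariate_log_hrs: dict = field(default_factory=lambda: {"age_baseline": 0.08, "sex_male": 0.35})
    hosp_covariate_log_hrs: dict = field(default_factory=lambda: {"age_baseline": 0.05, "sex_male": 0.20})
    #: Weibull baseline for time-from-baseline to death: H0(t) = (t/scale)^shape
    baseline_hazard: dict = field(default_factory=lambda: {"shape": 1.0, "scale": 260.0})
    hosp_hazard: dict = field(default_factory=lambda: {"shape": 1.0, "scale": 55.0})
    death_cause_weights: dict = field(default_factory=lambda: dict(DEATH_CAUSE_WEIGHTS))
    #: recruitment window and administrative censoring date; together with
    #: the loss rate these put the median follow-up near 12.65 years.
    baseline_start: str = "2007-09-01"
    baseline_end: str = "2010-10-01"
    admin_censor_date: str = "2022-02-01"
    loss_to_followup_rate: float = 0.004

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        for name, frac in [
            ("prop_male", self.prop_male),
            ("diet_recall_fraction", self.diet_recall_fraction),
            *[(f"prevalence[{k}]", v) for k, v in self.covariate_prevalences.items()],
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {frac}")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be > 0")
        for m, p in self.biomarker_params.items():
            if p["mean"] <= 0 or p["sd"] <= 0 or p.get("cap", 1.0) <= 0:
                raise ConfigError(f"biomarker {m!r}: location/scale/cap must be > 0")
        for hz in (self.baseline_hazard, self.hosp_hazard):
            if hz["shape"] <= 0 or hz["scale"] <= 0:
                raise ConfigError("hazard shape and scale must be > 0")
        if self.loss_to_followup_rate < 0:
            raise ConfigError("loss_to_followup_rate must be >= 0")
        lam, g = self.diet_inflammation_loading, self.cross_marker_loading
        if lam * lam + g * g >= 1.0:
            raise ConfigError("factor loadings too large: lam^2 + g^2 must be < 1")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def norm(v):
            if isinstance(v, tuple):
                return [norm(x) for x in v]
            if isinstance(v, list):
                return [norm(x) for x in v]
            if isinstance(v, dict):
                return {k: norm(x) for k, x in v.items()}
            return v

        return norm(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "age_range" in d and d["age_range"] is not None:
            d = {**d, "age_range": tuple(d["age_range"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the full configuration (stamped on outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
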