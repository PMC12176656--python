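"""Simulation configuration for synthetic dementia-biomarker cohorts.

The defaults encode the statistical structure of a community cohort of
dementia-free adults aged 60+ followed for up to 16 years: six positively
rank-correlated blood biomarkers with skewed marginals, baseline covariates
(age, sex, education, chronic diseases, APOE e4), an all-cause dementia
incidence near 1.82 per 100 person-years with ~58% of events being AD
dementia, competing death, administrative censoring and covariate-dependent
dropout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: Canonical biomarker column order used throughout the package.
BIOMARKERS = ["abeta_ratio", "ptau181", "ptau217", "ttau", "nfl", "gfap"]

#: Chronic-disease flag columns.
DISEASES = [
    "hypertension",
    "ischemic_heart_disease",
    "heart_failure",
    "atrial_fibrillation",
    "cerebrovascular_disease",
    "chronic_kidney_disease",
    "anaemia",
    "obesity",
]

EDUCATION_LEVELS = ["elementary", "high school", "university"]


def _default_spearman() -> np.ndarray:
    # Order: abeta_ratio, ptau181, ptau217, ttau, nfl, gfap.
    # The six strongest pairs follow the published correlation matrix; the
    # remaining pairs are weaker positive values consistent with "all
    # biomarkers correlated with each other".
    r = np.array(
        [
            [1.00, 0.15, 0.15, 0.20, 0.10, 0.10],
            [0.15, 1.00, 0.86, 0.61, 0.53, 0.42],
            [0.15, 0.86, 1.00, 0.62, 0.55, 0.45],
            [0.20, 0.61, 0.62, 1.00, 0.35, 0.30],
            [0.10, 0.53, 0.55, 0.35, 1.00, 0.65],
            [0.10, 0.42, 0.45, 0.30, 0.65, 1.00],
        ]
    )
    return r


def _default_marginals() -> dict[str, dict[str, float]]:
    # Log-normal (mu, sigma on the log scale) for concentrations in pg/ml;
    # logit-normal for the bounded amyloid ratio. Medians/IQRs are plausible
    # for serum assays in older adults and for the published cut-offs.
    return {
        "abeta_ratio": {"family": "logitnormal", "mu": -2.716, "sigma": 0.18},
        "ptau181": {"family": "lognormal", "mu": 0.095, "sigma": 0.50},
        "ptau217": {"family": "lognormal", "mu": -2.303, "sigma": 0.55},
        "ttau": {"family": "lognormal", "mu": -0.478, "sigma": 0.45},
        "nfl": {"family": "lognormal", "mu": 2.773, "sigma": 0.55},
        "gfap": {"family": "lognormal", "mu": 4.745, "sigma": 0.50},
    }


@dataclass
class CovariateParams:
    age_mean: float = 72.8
    age_sd: float = 10.6
    age_min: float = 60.0
    age_max: float = 101.0
    female_frac: float = 0.616
    education_probs: dict[str, float] = field(
        default_factory=lambda: {
            "elementary": 0.152,
            "high school": 0.494,
            "university": 0.354,
        }
    )
    disease_prev: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.685,
            "ischemic_heart_disease": 0.139,
            "heart_failure": 0.083,
            "atrial_fibrillation": 0.086,
            "cerebrovascular_disease": 0.060,
            "chronic_kidney_disease": 0.334,
            "anaemia": 0.110,
            "obesity": 0.129,
        }
    )
    extra_disease_mean: float = 2.0  # Poisson mean for diseases outside the 8 flags
    apoe_e4_frac: float = 0.292
    apoe_missing_frac: float = 0.0214
    mmse_mean: float = 28.6
    mmse_sd: float = 1.9
    memory_complaints_frac: float = 0.693
    memory_missing_frac: float = 0.0144


@dataclass
class HazardParams:
    """Weibull proportional-hazards dementia model.

    Cumulative baseline hazard H0(t) = scale * t**shape; the scale is left
    None and calibrated numerically so that the expected all-cause incidence
    rate matches ``target_ir`` per 100 person-years.

    The biomarker effect on the log hazard is threshold-shaped: flat below
    the 25th percentile of the marker's standardized (z) scale, then linear
    in z above it. For the amyloid ratio the z-score is negated first (low
    values are pathological).
    """

    shape: float = 1.4
    scale: float | None = None
    target_ir: float = 1.82  # per 100 person-years, all-cause dementia
    ad_fraction: float = 0.582
    log_hr_age_per10: float = 0.90
    log_hr_female: float = 0.10
    log_hr_education: dict[str, float] = field(
        default_factory=lambda: {"elementary": 0.0, "high school": -0.15, "university": -0.45}
    )
    log_hr_n_chronic: float = 0.06
    log_hr_apoe: float = 0.50
    biomarker_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "abeta_ratio": 0.30,
            "ptau181": 0.20,
            "ptau217": 0.30,
            "ttau": 0.05,
            "nfl": 0.30,
            "gfap": 0.25,
        }
    )
    threshold_z: float = -0.6745  # 25th percentile of a standard normal


@dataclass
class DeathParams:
    """Competing death: Weibull with age and disease-count dependence only
    (biomarker-independent by default, so cause-specific censoring is
    non-informative unless configured otherwise)."""

    shape: float = 1.5
    scale: float = 0.006
    log_hr_age_per10: float = 1.0
    log_hr_n_chronic: float = 0.06
    biomarker_log_hr: dict[str, float] = field(default_factory=dict)


@dataclass
class DropoutParams:
    """Logistic early-withdrawal model: younger, more educated, healthier
    participants are more likely to withdraw; withdrawal happens shortly
    after the baseline assessment (uniform within ``max_years``), so the
    retention decision is a baseline quantity rather than a follow-up one.
    """

    intercept: float = -2.3
    coef_age_per10: float = -0.55
    coef_female: float = 0.0
    coef_education: dict[str, float] = field(
        default_factory=lambda: {"elementary": 0.0, "high school": 0.15, "university": 0.45}
    )
    coef_n_chronic: float = -0.18
    biomarker_coef: dict[str, float] = field(default_factory=lambda: {"nfl": -0.15})
    max_years: float = 0.5


@dataclass
class SimConfig:
    n_participants: int = 2148
    seed: int = 1
    spearman_matrix: np.ndarray = field(default_factory=_default_spearman)
    marginal_params: dict[str, dict[str, float]] = field(default_factory=_default_marginals)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    hazard_params: HazardParams = field(default_factory=HazardParams)
    death_params: DeathParams = field(default_factory=DeathParams)
    dropout_params: DropoutParams = field(default_factory=DropoutParams)
    admin_censor_years: float = 16.0
    lod: dict[str, float] = field(
        default_factory=lambda: {
            "abeta_ratio": 0.005,
            "ptau181": 0.08,
            "ptau217": 0.006,
            "ttau": 0.06,
            "nfl": 0.5,
            "gfap": 2.0,
        }
    )

    def __post_init__(self) -> None:
        self.spearman_matrix = np.asarray(self.spearman_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        m = self.spearman_matrix
        if m.shape != (len(BIOMARKERS), len(BIOMARKERS)):
            raise ValueError(f"spearman_matrix must be {len(BIOMARKERS)}x{len(BIOMARKERS)}")
        if not np.allclose(m, m.T):
            raise ValueError("spearman_matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("spearman_matrix must have unit diagonal")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if np.any(off <= -1) or np.any(off >= 1):
            raise ValueError("off-diagonal Spearman entries must lie in (-1, 1)")
        if self.hazard_params.target_ir <= 0:
            raise ValueError("target incidence rate must be positive")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")
        cp = self.covariate_params
        for name, frac in [
            ("female_frac", cp.female_frac),
            ("apoe_e4_frac", cp.apoe_e4_frac),
            ("apoe_missing_frac", cp.apoe_missing_frac),
            ("memory_complaints_frac", cp.memory_complaints_frac),
            ("ad_fraction", self.hazard_params.ad_fraction),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not np.isclose(sum(cp.education_probs.values()), 1.0):
            raise ValueError("education_probs must sum to 1")

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["spearman_matrix"] = self.spearman_matrix.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        for key, sub in [
            ("covariate_params", CovariateParams),
            ("hazard_params", HazardParams),
            ("death_params", DeathParams),
            ("dropout_params", DropoutParams),
        ]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        """Read a SimConfig from a YAML or JSON file."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")
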