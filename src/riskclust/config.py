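"""Configuration models for the synthetic cohort and pipeline runs."""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .covariates import ALL_COVARIATES, CATEGORICAL_LEVELS, CONTINUOUS_FACTORS


class DiseaseProfile(BaseModel):
    """Ground-truth risk profile of one simulated disease.

    ``beta_male``/``beta_female`` map covariate names to log hazard ratios;
    unnamed covariates default to zero.  ``baseline_rate`` is the per-year
    baseline hazard, one value per year-of-birth stratum (a scalar is
    broadcast).  ``sex_specific`` marks diseases whose female profile was
    deliberately planted to differ from the male one (a BMI shift by
    default in the bundled configs).
    """

    disease_id: str
    cluster_id: str
    beta_male: dict[str, float] = Field(default_factory=dict)
    beta_female: dict[str, float] = Field(default_factory=dict)
    baseline_rate: list[float]
    sex_specific: bool = False

    @field_validator("baseline_rate", mode="before")
    @classmethod
    def _broadcastable(cls, v):
        if isinstance(v, (int, float)):
            return [float(v)]
        return v

    @field_validator("baseline_rate")
    @classmethod
    def _positive(cls, v):
        if not v or any(r <= 0 for r in v):
            raise ValueError("baseline_rate entries must be positive")
        return v

    @field_validator("beta_male", "beta_female")
    @classmethod
    def _known_names(cls, v):
        unknown = set(v) - set(ALL_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in beta: {sorted(unknown)}")
        return v

    def beta_vector(self, sex: str, names: list[str]) -> np.ndarray:
        beta = self.beta_male if sex == "male" else self.beta_female
        return np.array([beta.get(n, 0.0) for n in names])


class ContinuousFactorParams(BaseModel):
    """Per-sex mean/SD of a raw continuous measure before joint standardisation."""

    mean_male: float
    sd_male: float
    mean_female: float
    sd_female: float

    @field_validator("sd_male", "sd_female")
    @classmethod
    def _sd_positive(cls, v):
        if v <= 0:
            raise ValueError("SD must be positive")
        return v


DEFAULT_CONTINUOUS_PARAMS = {
    "bmi": ContinuousFactorParams(mean_male=27.8, sd_male=4.2, mean_female=27.1, sd_female=5.1),
    "height": ContinuousFactorParams(mean_male=175.6, sd_male=6.8, mean_female=162.4, sd_female=6.3),
    "sbp": ContinuousFactorParams(mean_male=141.0, sd_male=17.4, mean_female=135.2, sd_female=19.1),
}

DEFAULT_CATEGORICAL_PROBS = {
    "male": {
        "smoking": [0.55, 0.34, 0.11],
        "alcohol": [0.25, 0.26, 0.49],
        "walking_pace": [0.40, 0.53, 0.07],
        "education": [0.33, 0.25, 0.42],
        "deprivation": [1 / 3, 1 / 3, 1 / 3],
        "diabetes": [0.94, 0.06],
        "hrt": [1.0, 0.0],
        "children": [1.0, 0.0],
    },
    "female": {
        "smoking": [0.60, 0.31, 0.09],
        "alcohol": [0.35, 0.27, 0.38],
        "walking_pace": [0.39, 0.53, 0.08],
        "education": [0.32, 0.26, 0.42],
        "deprivation": [1 / 3, 1 / 3, 1 / 3],
        "diabetes": [0.96, 0.04],
        "hrt": [0.63, 0.37],
        "children": [0.16, 0.84],
    },
}


class SimulationConfig(BaseModel):
    """Full description of a synthetic cohort draw."""

    n_participants: int = Field(gt=0)
    seed: int = 0
    entry_age_range: tuple[float, float] = (40.0, 69.0)
    study_end_age_offset: float = Field(default=10.0, gt=0)
    yob_strata: int = Field(default=3, ge=1)
    disease_profiles: list[DiseaseProfile]
    cancer_hazard: float = Field(default=0.004, ge=0)
    continuous_factor_params: dict[str, ContinuousFactorParams] = Field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS_PARAMS)
    )
    categorical_factor_probs: dict[str, dict[str, list[float]]] = Field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_CATEGORICAL_PROBS))
    )

    @field_validator("entry_age_range")
    @classmethod
    def _age_range(cls, v):
        lo, hi = v
        if not (0 < lo < hi < 120):
            raise ValueError("entry_age_range must satisfy 0 < lo < hi < 120")
        return v

    @field_validator("disease_profiles")
    @classmethod
    def _nonempty_consistent(cls, v):
        if not v:
            raise ValueError("disease_profiles must be non-empty")
        ids = [p.disease_id for p in v]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate disease_id")
        return v

    @field_validator("categorical_factor_probs")
    @classmethod
    def _probs_sum(cls, v):
        for sex, factors in v.items():
            for name, probs in factors.items():
                if abs(sum(probs) - 1.0) > 1e-12:
                    raise ValueError(f"probabilities for {sex}/{name} do not sum to 1")
                if name in CATEGORICAL_LEVELS and len(probs) != len(CATEGORICAL_LEVELS[name]):
                    raise ValueError(f"wrong number of levels for {name}")
        return v

    @model_validator(mode="after")
    def _rates_match_strata(self):
        for p in self.disease_profiles:
            if len(p.baseline_rate) not in (1, self.yob_strata):
                raise ValueError(
                    f"{p.disease_id}: baseline_rate length must be 1 or yob_strata"
                )
        for f in CONTINUOUS_FACTORS:
            if f not in self.continuous_factor_params:
                raise ValueError(f"missing continuous_factor_params for {f}")
        return self

    def config_hash(self) -> str:
        """Stable content hash of the configuration (seed included)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config(
    n_participants: int = 50_000,
    n_diseases: int = 100,
    n_clusters: int = 12,
    seed: int = 0,
    n_sex_specific: Optional[int] = None,
    baseline_rate: float = 0.002,
    cluster_scale: float = 0.45,
    within_cluster_sd: float = 0.03,
    bmi_sex_shift: float = 0.3,
    min_separation: float = 0.5,
    **kwargs,
) -> SimulationConfig:
    """Study-condition generator: diseases in planted risk-profile clusters.

    Cluster centres live on the six comparison covariates, drawn from a
    zero-mean normal with SD ``cluster_scale`` and redrawn until all pairwise
    centre distances exceed ``min_separation``; each disease adds small
    within-cluster jitter plus its own weak adjustment-covariate effects.
    ``n_sex_specific`` diseases (default ≈8%) get a planted female-vs-male
    BMI shift of ``bmi_sex_shift``.  Baseline hazards rise across
    year-of-birth strata so stratified fitting is non-trivial.
    """
    if n_clusters > n_diseases:
        raise ValueError("n_clusters cannot exceed n_diseases")
    if n_sex_specific is None:
        n_sex_specific = max(1, round(0.08 * n_diseases)) if n_diseases >= 6 else 0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_001]))
    comparison = ["bmi", "height", "sbp", "walk_slow", "alcohol_regular", "smoke_current"]
    for _ in range(1000):
        centres = rng.normal(0.0, cluster_scale, size=(n_clusters, len(comparison)))
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        if n_clusters == 1 or d[np.triu_indices(n_clusters, 1)].min() > min_separation:
            break
    else:
        raise RuntimeError("could not place well-separated cluster centres")

    adjustment = ["smoke_previous", "alcohol_sometimes", "walk_average", "diabetes",
                  "edu_post16", "edu_age16", "deprivation_2", "deprivation_3"]
    members = [int(k) for k in np.sort(np.arange(n_diseases) % n_clusters)]
    sex_specific_ids = set(rng.choice(n_diseases, size=n_sex_specific, replace=False).tolist())
    strata_mult = np.linspace(0.8, 1.2, kwargs.get("yob_strata", 3))

    profiles = []
    for i in range(n_diseases):
        g = members[i]
        beta = dict(zip(comparison, centres[g] + rng.normal(0, within_cluster_sd, len(comparison))))
        # weaker secondary contrasts tied to the strong ones, plus small noise
        beta["smoke_previous"] = 0.4 * beta["smoke_current"] + rng.normal(0, 0.02)
        beta["alcohol_sometimes"] = 0.4 * beta["alcohol_regular"] + rng.normal(0, 0.02)
        beta["walk_average"] = 0.4 * beta["walk_slow"] + rng.normal(0, 0.02)
        for name in adjustment[3:]:
            beta[name] = float(rng.normal(0, 0.05))
        beta["diabetes"] = float(rng.normal(0, 0.15))
        beta_f = dict(beta)
        beta_f["hrt"] = float(rng.normal(0, 0.08))
        beta_f["children"] = float(rng.normal(0, 0.08))
        sex_specific = i in sex_specific_ids
        if sex_specific:
            beta_f["bmi"] = beta["bmi"] + bmi_sex_shift * (1 if rng.random() < 0.5 else -1)
        profiles.append(
            DiseaseProfile(
                disease_id=f"D{i:03d}",
                cluster_id=f"C{g:02d}",
                beta_male=beta,
                beta_female=beta_f,
                baseline_rate=(baseline_rate * strata_mult).tolist(),
                sex_specific=sex_specific,
            )
        )
    return SimulationConfig(
        n_participants=n_participants, seed=seed, disease_profiles=profiles, **kwargs
    )
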