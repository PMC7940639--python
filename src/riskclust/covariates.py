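"""Covariate schema shared by the cohort simulator and the survival fitter.

The model covariates follow the usual multimorbidity risk-factor set:
standardised continuous measures (BMI, height, systolic blood pressure),
lifestyle categories (smoking, alcohol, walking pace), diabetes, and the
adjustment covariates education, deprivation tertile and entry age, plus the
women-only covariates HRT use and having had children.  Categorical factors
are dummy-coded against fixed baselines: never smoker, rarely drink, brisk
walking pace, no diabetes, degree-level education, minimum deprivation
tertile, no HRT, no children.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Comparison parameters: one strong contrast per risk factor, used for
# marginalised disease comparisons and clustering.
COMPARISON_COVARIATES = [
    "bmi",
    "height",
    "sbp",
    "walk_slow",
    "alcohol_regular",
    "smoke_current",
]

# Remaining model covariates (adjustment / weaker contrasts).
ADJUSTMENT_COVARIATES = [
    "smoke_previous",
    "alcohol_sometimes",
    "walk_average",
    "diabetes",
    "edu_post16",
    "edu_age16",
    "deprivation_2",
    "deprivation_3",
    "entry_age_std",
]

FEMALE_ONLY_COVARIATES = ["hrt", "children"]

#: Full ordered covariate list; the female design appends HRT and children.
ALL_COVARIATES = COMPARISON_COVARIATES + ADJUSTMENT_COVARIATES + FEMALE_ONLY_COVARIATES

CONTINUOUS_FACTORS = ["bmi", "height", "sbp"]

CATEGORICAL_LEVELS = {
    "smoking": ["never", "previous", "current"],
    "alcohol": ["rarely", "sometimes", "regularly"],
    "walking_pace": ["brisk", "average", "slow"],
    "education": ["degree", "post16", "age16"],
    "deprivation": ["1", "2", "3"],
}

# Tertile-coded replacements for the continuous factors (sex-specific
# tertiles, lowest tertile baseline); the top-vs-bottom contrast stands in
# for the linear term in marginalised comparisons.
TERTILE_COMPARISON_COVARIATES = [
    "bmi_t3",
    "height_t3",
    "sbp_t3",
    "walk_slow",
    "alcohol_regular",
    "smoke_current",
]


def covariate_names(sex: str, coding: str = "linear") -> list[str]:
    """Ordered design-matrix column names for one sex and coding scheme."""
    if coding == "linear":
        cont = CONTINUOUS_FACTORS
    elif coding == "tertile":
        cont = [f"{f}_t{k}" for f in CONTINUOUS_FACTORS for k in (2, 3)]
    else:
        raise ValueError(f"unknown coding {coding!r}")
    names = cont + [c for c in COMPARISON_COVARIATES if c not in CONTINUOUS_FACTORS]
    names += ADJUSTMENT_COVARIATES
    if sex == "female":
        names += FEMALE_ONLY_COVARIATES
    return names


def comparison_subset(coding: str = "linear", include_bmi: bool = True) -> list[str]:
    """The marginal comparison subset for a coding; optionally without BMI."""
    names = COMPARISON_COVARIATES if coding == "linear" else TERTILE_COMPARISON_COVARIATES
    if not include_bmi:
        names = [n for n in names if not n.startswith("bmi")]
    return list(names)


def build_design(cohort: pd.DataFrame, sex: str, coding: str = "linear") -> pd.DataFrame:
    """Dummy-coded numeric design matrix for participants of one sex.

    ``cohort`` holds one row per participant with raw category labels and the
    jointly standardised continuous measures.  Entry age is standardised with
    the pooled (both-sex) mean/SD so male and female designs share a scale.
    """
    entry_mu = cohort["entry_age"].mean()
    entry_sd = cohort["entry_age"].std(ddof=0)
    sub = cohort[cohort["sex"] == sex]
    X = pd.DataFrame(index=sub.index)
    if coding == "linear":
        for f in CONTINUOUS_FACTORS:
            X[f] = sub[f].to_numpy(float)
    elif coding == "tertile":
        for f in CONTINUOUS_FACTORS:
            q = np.quantile(sub[f], [1 / 3, 2 / 3])
            t = np.digitize(sub[f], q)  # 0,1,2 = sex-specific tertile
            X[f + "_t2"] = (t == 1).astype(float)
            X[f + "_t3"] = (t == 2).astype(float)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    X["walk_slow"] = (sub["walking_pace"] == "slow").astype(float)
    X["alcohol_regular"] = (sub["alcohol"] == "regularly").astype(float)
    X["smoke_current"] = (sub["smoking"] == "current").astype(float)
    X["smoke_previous"] = (sub["smoking"] == "previous").astype(float)
    X["alcohol_sometimes"] = (sub["alcohol"] == "sometimes").astype(float)
    X["walk_average"] = (sub["walking_pace"] == "average").astype(float)
    X["diabetes"] = sub["diabetes"].astype(float)
    X["edu_post16"] = (sub["education"] == "post16").astype(float)
    X["edu_age16"] = (sub["education"] == "age16").astype(float)
    X["deprivation_2"] = (sub["deprivation"].astype(str) == "2").astype(float)
    X["deprivation_3"] = (sub["deprivation"].astype(str) == "3").astype(float)
    X["entry_age_std"] = (sub["entry_age"] - entry_mu) / entry_sd
    if sex == "female":
        X["hrt"] = sub["hrt"].astype(float)
        X["children"] = sub["children"].astype(float)
    return X[covariate_names(sex, coding)]
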