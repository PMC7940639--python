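"""Synthetic multimorbidity cohort generator.

Participants carry realistic risk-factor covariates; disease events are drawn
from a proportional-hazards model on the age timescale with a
piecewise-constant baseline hazard per year-of-birth stratum and a per-sex
linear predictor ``exp(beta' x)``.  Event ages are sampled by inverse-transform
sampling of the resulting (piecewise-)exponential survival function, so the
generator is exact, seedable and easy to check against closed forms.

Events before study entry are kept and flagged as prevalent (they feed the
prior-disease sensitivity analysis but never the incident event stream).
An independent exponential "cancer" clock, started at entry, right-censors
all subsequent disease events, as does the administrative end of follow-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .covariates import ALL_COVARIATES, CATEGORICAL_LEVELS, CONTINUOUS_FACTORS, build_design

STUDY_ENTRY_YEAR = 2008  # nominal calendar year of cohort entry


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort and its disease-event table.

    Returns ``(cohort, events)``.  ``cohort`` has one row per participant:
    id, sex, entry/end age, year-of-birth stratum, jointly standardised
    continuous measures and raw category labels.  ``events`` has one row per
    simulated event: participant_id, disease_id, event_age, prevalent flag
    (event before entry).  Cancer censoring events appear with
    ``disease_id == "cancer"``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1_000_001]))
    n = config.n_participants

    sex = np.where(rng.random(n) < 0.5, "male", "female")
    lo, hi = config.entry_age_range
    entry_age = rng.uniform(lo, hi, n)
    yob = STUDY_ENTRY_YEAR - entry_age
    # equal-occupancy year-of-birth strata
    edges = np.quantile(yob, np.linspace(0, 1, config.yob_strata + 1)[1:-1])
    yob_stratum = np.digitize(yob, edges)
    end_age = entry_age + config.study_end_age_offset

    cohort = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "sex": sex,
            "yob": np.round(yob).astype(int),
            "yob_stratum": yob_stratum,
            "entry_age": entry_age,
            "end_age": end_age,
        }
    )
    male = sex == "male"
    for f in CONTINUOUS_FACTORS:
        p = config.continuous_factor_params[f]
        raw = np.where(
            male,
            rng.normal(p.mean_male, p.sd_male, n),
            rng.normal(p.mean_female, p.sd_female, n),
        )
        # joint standardisation across men and women
        cohort[f] = (raw - raw.mean()) / raw.std(ddof=0)
    for factor, levels in CATEGORICAL_LEVELS.items():
        cohort[factor] = _draw_categorical(rng, config, factor, levels, sex)
    cohort["diabetes"] = _draw_categorical(rng, config, "diabetes", [0, 1], sex).astype(int)
    hrt = _draw_categorical(rng, config, "hrt", [0, 1], sex).astype(int)
    children = _draw_categorical(rng, config, "children", [0, 1], sex).astype(int)
    cohort["hrt"] = np.where(male, 0, hrt)
    cohort["children"] = np.where(male, 0, children)

    # censoring: administrative end of follow-up, or cancer clock from entry
    if config.cancer_hazard > 0:
        cancer_age = entry_age + rng.exponential(1.0 / config.cancer_hazard, n)
    else:
        cancer_age = np.full(n, np.inf)
    censor_age = np.minimum(end_age, cancer_age)

    event_frames = []
    designs = {s: build_design(cohort, s, "linear") for s in ("male", "female")}
    order = {s: cohort.index[cohort["sex"] == s] for s in ("male", "female")}
    for profile in config.disease_profiles:
        rates = np.asarray(profile.baseline_rate)
        if rates.size == 1:
            rates = np.repeat(rates, config.yob_strata)
        t_event = np.empty(n)
        for s in ("male", "female"):
            idx = order[s]
            X = designs[s]
            beta = profile.beta_vector(s, list(X.columns))
            lam = rates[yob_stratum[idx]] * np.exp(X.to_numpy() @ beta)
            t_event[idx] = rng.exponential(1.0 / lam)
        prevalent = t_event <= entry_age
        incident = (t_event > entry_age) & (t_event <= censor_age)
        keep = prevalent | incident
        event_frames.append(
            pd.DataFrame(
                {
                    "participant_id": cohort.loc[keep, "participant_id"],
                    "disease_id": profile.disease_id,
                    "event_age": t_event[keep],
                    "prevalent": prevalent[keep],
                }
            )
        )
    has_cancer = cancer_age < end_age
    event_frames.append(
        pd.DataFrame(
            {
                "participant_id": cohort.loc[has_cancer, "participant_id"],
                "disease_id": "cancer",
                "event_age": cancer_age[has_cancer],
                "prevalent": False,
            }
        )
    )
    events = (
        pd.concat(event_frames, ignore_index=True)
        .sort_values(["disease_id", "participant_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return cohort, events


def planted_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth export: one row per disease and sex.

    Columns: disease_id, sex, cluster_id, sex_specific, and the true log
    hazard ratio for every model covariate (women-only covariates are NaN
    for men, where they are structurally absent).
    """
    rows = []
    for profile in config.disease_profiles:
        for s in ("male", "female"):
            row = {
                "disease_id": profile.disease_id,
                "sex": s,
                "cluster_id": profile.cluster_id,
                "sex_specific": profile.sex_specific,
            }
            beta = profile.beta_male if s == "male" else profile.beta_female
            for name in ALL_COVARIATES:
                if s == "male" and name in ("hrt", "children"):
                    row[name] = np.nan
                else:
                    row[name] = beta.get(name, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def _draw_categorical(rng, config, factor, levels, sex):
    n = len(sex)
    out = np.empty(n, dtype=object)
    for s in ("male", "female"):
        mask = sex == s
        probs = config.categorical_factor_probs[s][factor]
        out[mask] = rng.choice(np.asarray(levels, dtype=object), size=mask.sum(), p=probs)
    return out
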