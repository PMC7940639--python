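"""Shared fixtures: simulated cohorts and fitted batteries, built once per session.

Problem sizes are scaled so the whole suite runs in minutes: fewer diseases
and participants than the generator's default study conditions, but the same
data-generating process and the same fitting machinery.
"""

from __future__ import annotations

import numpy as np
import pytest

from riskclust import default_config, fit_all, simulate_cohort
from riskclust.config import DiseaseProfile, SimulationConfig


@pytest.fixture(scope="session")
def separated_setup():
    """Six diseases, each with its own well-separated profile; two of them
    carry a planted female-vs-male BMI shift of 0.3."""
    cfg = default_config(
        n_participants=78_000,
        n_diseases=6,
        n_clusters=6,
        seed=11,
        baseline_rate=0.008,
        min_separation=0.9,
        n_sex_specific=2,
        bmi_sex_shift=0.3,
    )
    cohort, events = simulate_cohort(cfg)
    fits = fit_all(cohort, events)
    return cfg, cohort, events, fits


def null_config(n_participants: int, seed: int, n_diseases: int = 1,
                baseline_rate: float = 0.004, cancer_hazard: float = 0.004,
                **kwargs) -> SimulationConfig:
    """Cohort whose diseases all have zero log hazard ratios."""
    profiles = [
        DiseaseProfile(disease_id=f"N{i:02d}", cluster_id="C0",
                       baseline_rate=baseline_rate)
        for i in range(n_diseases)
    ]
    return SimulationConfig(
        n_participants=n_participants, seed=seed, disease_profiles=profiles,
        cancer_hazard=cancer_hazard, **kwargs,
    )


def single_effect_config(n_participants: int, seed: int, covariate: str,
                         beta: float, baseline_rate: float = 0.005,
                         **kwargs) -> SimulationConfig:
    """One disease with a single non-zero log hazard ratio (both sexes)."""
    profile = DiseaseProfile(
        disease_id="D0", cluster_id="C0",
        beta_male={covariate: beta}, beta_female={covariate: beta},
        baseline_rate=baseline_rate,
    )
    return SimulationConfig(
        n_participants=n_participants, seed=seed, disease_profiles=[profile], **kwargs
    )


@pytest.fixture(scope="session")
def coverage_battery():
    """200 replicate cohorts with a planted BMI effect of log 2, male fit only.

    Returns (true_beta, estimates, standard_errors, n_cases) arrays used for
    both Wald-interval coverage and bias checks.
    """
    from riskclust.cox import fit_disease

    true_beta = np.log(2)
    est, se, cases = [], [], []
    for rep in range(200):
        cfg = single_effect_config(60_000, seed=10_000 + rep, covariate="bmi",
                                   beta=true_beta, baseline_rate=0.03)
        cohort, events = simulate_cohort(cfg)
        f = fit_disease(cohort, events, "D0", "male")
        assert f.ok
        i = f.covariate_names.index("bmi")
        est.append(f.mu_hat[i])
        se.append(np.sqrt(f.sigma_hat[i, i]))
        cases.append(f.n_cases)
    return true_beta, np.array(est), np.array(se), np.array(cases)


@pytest.fixture(scope="session")
def null_pvalue_battery():
    """Global chi-square and Schoenfeld p-values across 60 null replicates."""
    from riskclust.cox import fit_disease

    chi2_p, ph_p = [], []
    for rep in range(60):
        cfg = null_config(6_000, seed=20_000 + rep, baseline_rate=0.006)
        cohort, events = simulate_cohort(cfg)
        f = fit_disease(cohort, events, "N00", "male")
        if f.ok:
            chi2_p.append(f.global_chi2_p)
            ph_p.append(f.ph_test_p)
    return np.array(chi2_p), np.array(ph_p)


def clustered_config(seed: int) -> SimulationConfig:
    """Eight diseases in three planted clusters with strong separation."""
    return default_config(
        n_participants=12_000,
        n_diseases=8,
        n_clusters=3,
        seed=seed,
        baseline_rate=0.006,
        cluster_scale=0.6,
        min_separation=1.2,
        n_sex_specific=0,
    )
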