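"""Simulate a small synthetic multimorbidity cohort and inspect it.

Draws participants with realistic risk-factor covariates, then disease event
ages from a proportional-hazards model on the age timescale with planted
per-disease risk profiles.
"""

from riskclust import default_config, planted_truth, simulate_cohort

config = default_config(n_participants=10_000, n_diseases=6, n_clusters=3, seed=1,
                        baseline_rate=0.005)
cohort, events = simulate_cohort(config)

incident = events[~events["prevalent"] & (events["disease_id"] != "cancer")]
print(f"participants: {len(cohort)}")
print(f"incident disease events: {len(incident)}")
print(f"cancer censoring events: {(events['disease_id'] == 'cancer').sum()}")
print("\nincident cases per disease (needs >= 50 for a fit):")
print(incident.groupby("disease_id").size().to_string())
print("\npooled mean/SD of standardised BMI (should be ~0/1):",
      round(cohort['bmi'].mean(), 3), "/", round(cohort['bmi'].std(), 3))

truth = planted_truth(config)
print("\nplanted ground truth (one row per disease and sex):")
print(truth[["disease_id", "sex", "cluster_id", "bmi", "smoke_current"]]
      .head(6).to_string(index=False))
# The beta columns are the true log hazard ratios the fitter should recover.
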