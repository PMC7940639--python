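"""End-to-end orchestration: simulate -> fit -> compare -> cluster -> stability.

A single :class:`RunConfig` drives every stage; all intermediates are
persisted as plain-text artifacts (CSV/JSON/Newick) under the output
directory, and the final :class:`RunReport` aggregates the headline numbers:
the selection cascade, opposite-sex identification fractions, sex-difference
counts with and without BMI, the selected cluster count, the smallest
non-significant cut, and pair-overlap stability for each sensitivity rerun.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field
from scipy.cluster.hierarchy import fcluster

from . import io
from .clustering import (
    compare_clusterings,
    hierarchical_cluster,
    heatmap_values,
    linkage_to_newick,
    select_k,
)
from .config import SimulationConfig, default_config
from .covariates import comparison_subset
from .cox import fit_all, run_selection
from .paramspace import (
    distance_matrix,
    identification_summary,
    identify_partners,
    marginalise,
    sex_difference_scan,
    split_label,
)
from .simulate import planted_truth, simulate_cohort


class RunConfig(BaseModel):
    """Configuration of a full pipeline run."""

    out_dir: str
    seed: int = 0
    simulation: Optional[SimulationConfig] = None  # None -> default study conditions
    cohort_dir: Optional[str] = None  # load instead of simulating
    coding: str = "linear"
    subset: str = "default"  # "default" | "no-bmi"
    alpha: float = 0.05
    k_range: Optional[list[int]] = None
    override_k: Optional[int] = None
    sensitivity_prior_exclusion: bool = False
    sensitivity_tertile: bool = False
    n_participants: int = Field(default=50_000, gt=0)
    n_diseases: int = Field(default=100, gt=0)
    n_clusters: int = Field(default=12, gt=0)


def combinatorics_note(n_factors: int, n_levels: int) -> int:
    """Distinct risk-factor profiles: n_levels ** n_factors.

    Seven trinary factors already admit 3**7 = 2187 distinct profiles, which
    is why a handful of measured risk factors can be surprisingly specific to
    individual diseases.
    """
    if n_factors < 0 or n_levels < 1:
        raise ValueError("need n_factors >= 0 and n_levels >= 1")
    return n_levels**n_factors


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also persisted)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: cohort ---------------------------------------------------
    if config.cohort_dir is not None:
        cohort, events = io.read_cohort(config.cohort_dir)
        sim_config = None
    else:
        sim_config = config.simulation or default_config(
            n_participants=config.n_participants,
            n_diseases=config.n_diseases,
            n_clusters=config.n_clusters,
            seed=config.seed,
        )
        cohort, events = simulate_cohort(sim_config)
        io.write_cohort(cohort, events, sim_config, out / "cohort")
        planted_truth(sim_config).to_csv(out / "planted_truth.csv", index=False)

    # --- stage 2: per-disease fits and selection ---------------------------
    fits = fit_all(cohort, events, coding=config.coding)
    io.write_fits(fits, out / "fits.csv", coding=config.coding)
    selection = run_selection(fits, alpha=config.alpha)
    io.write_json(selection.as_dict(), out / "selection_report.json")

    included = set(selection.included)
    ok_fits = [f for f in fits if f.ok and f.disease_id in included]
    subset = comparison_subset(config.coding, include_bmi=(config.subset != "no-bmi"))
    marginals = [marginalise(f, subset) for f in ok_fits]

    if not marginals:
        report = {
            "seed": config.seed,
            "coding": config.coding,
            "selection": selection.as_dict(),
            "identification": None,
            "sex_differences": None,
            "clustering": None,
            "stability": {},
            "profile_combinatorics": {"factors_7_levels_3": combinatorics_note(7, 3)},
            "artifacts": sorted(
                str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            ),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report

    # --- stage 3: comparisons ----------------------------------------------
    dm = distance_matrix(marginals)
    io.write_distance_matrix(dm, out / "distance_matrix.csv")
    partners = identify_partners(dm)
    partners.to_csv(out / "partners.csv")
    ident = identification_summary(partners)

    scan = sex_difference_scan(ok_fits, subset, alpha=config.alpha)
    scan.to_csv(out / "sex_differences.csv", index=False)
    subset_nb = comparison_subset(config.coding, include_bmi=False)
    scan_nb = sex_difference_scan(ok_fits, subset_nb, alpha=config.alpha)
    scan_nb.to_csv(out / "sex_differences_no_bmi.csv", index=False)

    # --- stage 4: clustering (sex-different diseases removed first) --------
    flagged = set(scan.loc[scan["flagged"], "disease_id"])
    cluster_marginals = [m for m in marginals if m.disease_id not in flagged]
    cdm = dm.loc[
        [f"{m.disease_id}|{m.sex}" for m in cluster_marginals],
        [f"{m.disease_id}|{m.sex}" for m in cluster_marginals],
    ]
    Z = hierarchical_cluster(cdm)
    clustering = select_k(
        Z, cluster_marginals, k_range=config.k_range,
        alpha=config.alpha, override_k=config.override_k,
    )
    clustering.elbow_curve.to_csv(out / "elbow_curve.csv", index=False)
    labels = clustering.labels_at_selected_k
    pd.Series(labels, name="cluster").rename_axis("entry").to_csv(out / "clusters.csv")
    (out / "dendrogram.nwk").write_text(linkage_to_newick(Z, clustering.entry_labels))
    heatmap_values(cluster_marginals).to_csv(out / "heatmap.csv")

    # --- stage 5: sensitivity reruns ---------------------------------------
    stability = {}
    if config.sensitivity_prior_exclusion:
        stability["prior_exclusion"] = _stability_rerun(
            config, cohort, events, labels, clustering.selected_k, subset,
            coding=config.coding, exclusion_from=labels, out=out / "rerun_prior",
        )
    if config.sensitivity_tertile and config.coding == "linear":
        stability["tertile"] = _stability_rerun(
            config, cohort, events, labels, clustering.selected_k,
            comparison_subset("tertile", include_bmi=(config.subset != "no-bmi")),
            coding="tertile", exclusion_from=None, out=out / "rerun_tertile",
        )

    report = {
        "seed": config.seed,
        "coding": config.coding,
        "selection": selection.as_dict(),
        "identification": ident,
        "sex_differences": {
            "n_tested": int(len(scan)),
            "n_flagged": int(scan["flagged"].sum()) if len(scan) else 0,
            "flagged_fraction": float(scan["flagged"].mean()) if len(scan) else float("nan"),
            "n_flagged_no_bmi": int(scan_nb["flagged"].sum()) if len(scan_nb) else 0,
            "flagged_fraction_no_bmi": float(scan_nb["flagged"].mean()) if len(scan_nb) else float("nan"),
        },
        "clustering": {
            "n_entries": len(clustering.entry_labels),
            "selected_k": clustering.selected_k,
            "min_nonsignificant_k": clustering.min_nonsignificant_k,
        },
        "stability": stability,
        "profile_combinatorics": {"factors_7_levels_3": combinatorics_note(7, 3)},
        "artifacts": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stability_rerun(config, cohort, events, main_labels, k, subset, coding,
                     exclusion_from, out) -> dict:
    """Refit under a sensitivity variant, recluster at the same k, compare."""
    diseases = sorted({split_label(e)[0] for e in main_labels})
    exclusion_sets = None
    if exclusion_from is not None:
        cluster_of: dict[str, set] = {}
        for entry, c in exclusion_from.items():
            d, _ = split_label(entry)
            cluster_of.setdefault(d, set()).add(c)
        exclusion_sets = {
            d: {
                other
                for other, cs in cluster_of.items()
                if cs & cluster_of.get(d, set()) and other != d
            }
            for d in diseases
        }
    fits = fit_all(cohort, events, coding=coding, disease_ids=diseases,
                   exclusion_sets=exclusion_sets)
    ok = [f for f in fits if f.ok]
    both = {d for d in diseases
            if {f.sex for f in ok if f.disease_id == d} == {"male", "female"}}
    marginals = [marginalise(f, subset) for f in ok if f.disease_id in both]
    entries = [f"{m.disease_id}|{m.sex}" for m in marginals]
    common = [e for e in entries if e in main_labels]
    marginals = [m for m in marginals if f"{m.disease_id}|{m.sex}" in set(common)]
    dm = distance_matrix(marginals)
    Z = hierarchical_cluster(dm)
    flat = dict(zip(
        dm.index,
        (int(c) for c in fcluster(Z, t=min(k, len(common)), criterion="maxclust")),
    ))
    main_sub = {e: main_labels[e] for e in common}
    comp = compare_clusterings(main_sub, flat)
    out.mkdir(parents=True, exist_ok=True)
    io.write_distance_matrix(dm, out / "distance_matrix.csv")
    io.write_fits(fits, out / "fits.csv", coding=coding)
    result = {
        "n_entries": len(common),
        "n_a": comp.n_a, "n_b": comp.n_b, "n_ab": comp.n_ab,
        "p_ab": comp.p_ab,
        "sensitive_entries": comp.sensitive_entries,
    }
    io.write_json(result, out / "stability.json")
    return result
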