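"""Plain-text persistence: CSV tables, JSON configs/reports, Newick trees."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .cox import DiseaseFit

FLOAT_FMT = "%.10g"


def write_cohort(
    cohort: pd.DataFrame, events: pd.DataFrame, config: SimulationConfig, outdir: str | Path
) -> None:
    """Write cohort.csv, events.csv, config.json and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False, float_format=FLOAT_FMT)
    events.to_csv(outdir / "events.csv", index=False, float_format=FLOAT_FMT)
    (outdir / "config.json").write_text(config.model_dump_json(indent=2))
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "n_participants": config.n_participants,
                "n_diseases": len(config.disease_profiles)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    cohort = pd.read_csv(indir / "cohort.csv", dtype={"deprivation": str})
    events = pd.read_csv(indir / "events.csv")
    events["prevalent"] = events["prevalent"].astype(bool)
    return cohort, events


def write_fits(fits: Sequence[DiseaseFit], path: str | Path, coding: str = "linear") -> None:
    """One CSV record per disease-sex fit plus a covariate-order sidecar."""
    path = Path(path)
    rows = []
    names: dict[str, list[str]] = {}
    for f in fits:
        if f.ok:
            names.setdefault(f.sex, f.covariate_names)
        rows.append({
            "disease_id": f.disease_id,
            "sex": f.sex,
            "n_cases": f.n_cases,
            "ok": f.ok,
            "fail_reason": f.fail_reason or "",
            "global_chi2_p": f.global_chi2_p,
            "ph_test_p": f.ph_test_p,
            "selection_flags": json.dumps(f.selection_flags),
            "mu": json.dumps(f.mu_hat.tolist()) if f.ok else "",
            "sigma": json.dumps(f.sigma_hat.tolist()) if f.ok else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    sidecar = {"coding": coding, "covariate_names": names}
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2))


def read_fits(path: str | Path) -> tuple[list[DiseaseFit], dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    table = pd.read_csv(path, keep_default_na=False)
    fits = []
    for _, r in table.iterrows():
        ok = str(r["ok"]) in ("True", "true", "1")
        fit = DiseaseFit(
            disease_id=str(r["disease_id"]),
            sex=str(r["sex"]),
            n_cases=int(r["n_cases"]),
            mu_hat=np.array(json.loads(r["mu"])) if ok else None,
            sigma_hat=np.array(json.loads(r["sigma"])) if ok else None,
            covariate_names=meta["covariate_names"][str(r["sex"])] if ok else None,
            global_chi2_p=float(r["global_chi2_p"]) if r["global_chi2_p"] != "" else None,
            ph_test_p=float(r["ph_test_p"]) if r["ph_test_p"] != "" else None,
            ok=ok,
            fail_reason=str(r["fail_reason"]) or None,
        )
        fit.selection_flags = json.loads(r["selection_flags"])
        fits.append(fit)
    return fits, meta


def write_distance_matrix(dm: pd.DataFrame, path: str | Path) -> None:
    dm.to_csv(path, float_format=FLOAT_FMT)


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
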