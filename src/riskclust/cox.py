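"""Per-disease, per-sex proportional-hazards fitting and the selection cascade.

Each disease is fitted separately for men and women with lifelines'
``CoxPHFitter`` (Efron ties): age is the time axis, participants enter the
risk set at their study entry age (left truncation), fits are stratified by
year-of-birth stratum, and follow-up is right-censored at the administrative
end of study or at a prior cancer event.  The fitted log-hazard-ratio vector
and its covariance matrix are the disease's summary for all downstream
comparisons.

The selection cascade applies, in order: fit success with a 50-case floor;
a covariance-eigenvalue outlier screen; a Bonferroni-adjusted multivariate
chi-square significance test; a Benjamini-Hochberg-adjusted global Schoenfeld
proportional-hazards test (diseases failing it are excluded); and finally the
requirement that a disease survive in both sexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .covariates import build_design

CASE_FLOOR = 50
EIGEN_SD_THRESHOLD = 2.5


@dataclass
class DiseaseFit:
    """MLE summary of one disease in one sex."""

    disease_id: str
    sex: str
    n_cases: int
    mu_hat: Optional[np.ndarray] = None
    sigma_hat: Optional[np.ndarray] = None
    covariate_names: Optional[list[str]] = None
    global_chi2_p: Optional[float] = None
    ph_test_p: Optional[float] = None
    ok: bool = False
    fail_reason: Optional[str] = None
    selection_flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ok:
            p = len(self.covariate_names)
            assert self.mu_hat.shape == (p,) and self.sigma_hat.shape == (p, p)


@dataclass
class SelectionReport:
    """Stage-by-stage survivor counts and per-disease exclusion reasons."""

    stage_counts: dict[str, dict[str, int]]  # sex -> stage -> count
    exclusion_reasons: dict[str, dict[str, str]]  # sex -> disease -> reason
    included: list[str]  # unisex disease set

    def as_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "exclusion_reasons": self.exclusion_reasons,
            "included": self.included,
        }


def fit_disease(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    disease_id: str,
    sex: str,
    coding: str = "linear",
    exclusions: Optional[set[str]] = None,
) -> DiseaseFit:
    """Fit one disease in one sex; see :func:`fit_all` for batch fitting."""
    X = build_design(cohort, sex, coding)
    censor = _censor_ages(cohort, events)
    return _fit_one(cohort, events, X, censor, disease_id, sex, exclusions)


def fit_all(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    coding: str = "linear",
    disease_ids: Optional[list[str]] = None,
    exclusion_sets: Optional[dict[str, set[str]]] = None,
) -> list[DiseaseFit]:
    """Fit every disease in both sexes.

    ``exclusion_sets`` optionally maps a disease to the set of diseases whose
    prior occurrence disqualifies a participant from its risk set (the
    prior-disease sensitivity analysis).
    """
    if disease_ids is None:
        disease_ids = sorted(d for d in events["disease_id"].unique() if d != "cancer")
    censor = _censor_ages(cohort, events)
    fits = []
    for sex in ("male", "female"):
        X = build_design(cohort, sex, coding)
        for d in disease_ids:
            excl = exclusion_sets.get(d) if exclusion_sets else None
            fits.append(_fit_one(cohort, events, X, censor, d, sex, excl))
    return fits


def _censor_ages(cohort: pd.DataFrame, events: pd.DataFrame) -> pd.Series:
    """Per-participant censoring age: end of study or first cancer event."""
    censor = cohort.set_index("participant_id")["end_age"].copy()
    cancer = events[events["disease_id"] == "cancer"]
    if len(cancer):
        first = cancer.groupby("participant_id")["event_age"].min()
        censor.loc[first.index] = np.minimum(censor.loc[first.index], first)
    return censor


def _fit_one(cohort, events, X, censor, disease_id, sex, exclusions) -> DiseaseFit:
    sub = cohort[cohort["sex"] == sex].set_index("participant_id")
    ev = events[events["disease_id"] == disease_id]
    ev = ev[ev["participant_id"].isin(sub.index)]
    prevalent_ids = set(ev.loc[ev["prevalent"], "participant_id"])
    incident = ev[~ev["prevalent"]].set_index("participant_id")["event_age"]

    keep = sub.index.difference(prevalent_ids)
    cens = censor.loc[keep]
    stop = cens.copy()
    inc = incident.reindex(keep)
    has_event = inc.notna() & (inc <= cens)
    stop[has_event] = inc[has_event]

    if exclusions:
        prior = events[
            events["disease_id"].isin(set(exclusions) - {disease_id})
            & events["participant_id"].isin(keep)
        ]
        first_other = prior.groupby("participant_id")["event_age"].min()
        first_other = first_other.reindex(keep)
        drop = first_other.notna() & (first_other < stop)
        keep = keep[~drop.to_numpy()]
        stop, has_event = stop.loc[keep], has_event.loc[keep]

    entry = sub.loc[keep, "entry_age"]
    valid = stop > entry
    keep = keep[valid.to_numpy()]
    n_cases = int(has_event.loc[keep].sum())
    if n_cases < CASE_FLOOR:
        fit = DiseaseFit(disease_id, sex, n_cases, ok=False, fail_reason="insufficient cases")
        fit.selection_flags["case_floor"] = False
        return fit

    # X is indexed by cohort row position; re-key it by participant_id
    df = X.copy()
    df.index = cohort.loc[X.index, "participant_id"]
    df = df.loc[keep]
    names = list(df.columns)
    df["entry_age"] = entry.loc[keep]
    df["stop"] = stop.loc[keep]
    df["event"] = has_event.loc[keep].astype(int)
    df["yob_stratum"] = sub.loc[keep, "yob_stratum"]

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="stop",
                event_col="event",
                entry_col="entry_age",
                strata=["yob_stratum"],
            )
        mu = cph.params_.reindex(names).to_numpy()
        sigma = cph.variance_matrix_.reindex(index=names, columns=names).to_numpy()
        if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(sigma)):
            raise ValueError("non-finite estimates")
        np.linalg.cholesky(sigma)  # positive-definiteness check
    except Exception:
        fit = DiseaseFit(disease_id, sex, n_cases, ok=False, fail_reason="fit failure")
        fit.selection_flags["case_floor"] = True
        fit.selection_flags["converged"] = False
        return fit

    fit = DiseaseFit(
        disease_id, sex, n_cases,
        mu_hat=mu, sigma_hat=sigma, covariate_names=names, ok=True,
    )
    fit.selection_flags["case_floor"] = True
    fit.selection_flags["converged"] = True
    fit.global_chi2_p = global_significance_test(fit)
    fit.ph_test_p = _schoenfeld_global_p(df, names, mu, sigma)
    return fit


def global_significance_test(fit: DiseaseFit) -> float:
    """Multivariate chi-square test that all fitted log HRs are zero.

    Statistic ``mu' Sigma^{-1} mu`` referred to chi-square with one degree of
    freedom per parameter.
    """
    mu, sigma = fit.mu_hat, fit.sigma_hat
    try:
        z = np.linalg.solve(sigma, mu)
    except np.linalg.LinAlgError as e:
        raise ValueError("degenerate covariance") from e
    stat = float(mu @ z)
    return float(stats.chi2.sf(stat, len(mu)))


def schoenfeld_residuals(
    df: pd.DataFrame, names: list[str], beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Schoenfeld residuals under delayed entry and stratification.

    For each event at age t, the residual is the event subject's covariate
    vector minus the hazard-weighted mean over the stratum's risk set
    {entry < t <= stop}.  Risk-set sums are computed as suffix sums over
    subjects sorted by stop age minus suffix sums over subjects sorted by
    entry age.  Returns (event_ages, residual_matrix).
    """
    out_t, out_s = [], []
    p = len(names)
    for _, g in df.groupby("yob_stratum"):
        X = g[names].to_numpy()
        entry = g["entry_age"].to_numpy()
        stop = g["stop"].to_numpy()
        ev = g["event"].to_numpy().astype(bool)
        if not ev.any():
            continue
        w = np.exp(X @ beta)
        wx = w[:, None] * X
        o_stop = np.argsort(stop)
        o_entry = np.argsort(entry)
        stop_sorted = stop[o_stop]
        entry_sorted = entry[o_entry]
        cw_stop = np.concatenate([np.cumsum(w[o_stop][::-1])[::-1], [0.0]])
        cwx_stop = np.vstack([np.cumsum(wx[o_stop][::-1], axis=0)[::-1], np.zeros((1, p))])
        cw_entry = np.concatenate([np.cumsum(w[o_entry][::-1])[::-1], [0.0]])
        cwx_entry = np.vstack([np.cumsum(wx[o_entry][::-1], axis=0)[::-1], np.zeros((1, p))])
        t_ev = stop[ev]
        i_stop = np.searchsorted(stop_sorted, t_ev, side="left")
        i_entry = np.searchsorted(entry_sorted, t_ev, side="left")
        denom = cw_stop[i_stop] - cw_entry[i_entry]
        xbar = (cwx_stop[i_stop] - cwx_entry[i_entry]) / denom[:, None]
        out_t.append(t_ev)
        out_s.append(X[ev] - xbar)
    return np.concatenate(out_t), np.vstack(out_s)


def _schoenfeld_global_p(
    df: pd.DataFrame, names: list[str], beta: np.ndarray, sigma: np.ndarray
) -> float:
    """Global Grambsch-Therneau test of the proportional-hazards assumption.

    Uses the Schoenfeld residuals S (one row per event) against the identity
    time transform g(t)=t: with centred g, u = S'g and
    Var(u) ~ (sum g^2 / d) * I, the statistic d/(sum g^2) * u' Sigma u is
    chi-square with one degree of freedom per covariate.
    """
    times, S = schoenfeld_residuals(df, names, beta)
    if len(times) == 0 or np.ptp(times) == 0:
        raise ValueError("degenerate residuals")
    d = len(times)
    g = times - times.mean()
    u = S.T @ g
    stat = d / float(g @ g) * float(u @ sigma @ u)
    return float(stats.chi2.sf(stat, S.shape[1]))


def eigenvalue_screen(fits: list[DiseaseFit]) -> dict[tuple[str, str], bool]:
    """Flag fits whose covariance eigenvalues are outlying.

    For each successful fit take the log of its largest and smallest
    covariance eigenvalues; a fit is flagged when its log-largest exceeds the
    across-fit mean by more than 2.5 SDs, or its log-smallest falls below the
    across-fit mean by more than 2.5 SDs (means and SDs computed with all
    fits, outliers included).  Returns ``{(disease_id, sex): flagged}``.
    """
    ok = [f for f in fits if f.ok]
    if len(ok) < 3:
        raise ValueError("eigenvalue screen needs at least 3 successful fits")
    log_max = np.array([np.log(np.linalg.eigvalsh(f.sigma_hat)[-1]) for f in ok])
    log_min = np.array([np.log(np.linalg.eigvalsh(f.sigma_hat)[0]) for f in ok])
    flags = {}
    hi = log_max > log_max.mean() + EIGEN_SD_THRESHOLD * log_max.std(ddof=1)
    lo = log_min < log_min.mean() - EIGEN_SD_THRESHOLD * log_min.std(ddof=1)
    if log_max.std(ddof=1) == 0:
        hi = np.zeros(len(ok), bool)
    if log_min.std(ddof=1) == 0:
        lo = np.zeros(len(ok), bool)
    for f, h, l in zip(ok, hi, lo):
        flags[(f.disease_id, f.sex)] = bool(h or l)
    return flags


def run_selection(fits: list[DiseaseFit], alpha: float = 0.05) -> SelectionReport:
    """Apply the full selection cascade and report survivors per stage."""
    by_sex = {s: [f for f in fits if f.sex == s] for s in ("male", "female")}
    reasons: dict[str, dict[str, str]] = {"male": {}, "female": {}}
    counts: dict[str, dict[str, int]] = {}
    survivors: dict[str, set[str]] = {}

    for sex, sex_fits in by_sex.items():
        stage = {}
        ok_fits = []
        for f in sex_fits:
            if f.ok:
                ok_fits.append(f)
            else:
                reasons[sex][f.disease_id] = f.fail_reason or "fit failure"
        stage["fit_success"] = len(ok_fits)

        if len(ok_fits) >= 3:
            eflags = eigenvalue_screen(ok_fits)
        else:
            eflags = {(f.disease_id, f.sex): False for f in ok_fits}
        screened = []
        for f in ok_fits:
            f.selection_flags["eigen_screen"] = not eflags[(f.disease_id, f.sex)]
            if eflags[(f.disease_id, f.sex)]:
                reasons[sex][f.disease_id] = "eigenvalue outlier"
            else:
                screened.append(f)
        stage["eigen_screen"] = len(screened)

        m = len(screened)  # Bonferroni family: diseases tested within this sex
        signif = []
        for f in screened:
            passed = f.global_chi2_p is not None and f.global_chi2_p * m < alpha
            f.selection_flags["bonferroni_significant"] = passed
            if passed:
                signif.append(f)
            else:
                reasons[sex][f.disease_id] = "not significant after Bonferroni"
        stage["bonferroni"] = len(signif)

        if signif:
            pvals = np.array([f.ph_test_p for f in signif])
            reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        else:
            reject = np.array([], dtype=bool)
        ph_ok = []
        for f, rej in zip(signif, reject):
            f.selection_flags["ph_test"] = not rej
            if rej:
                reasons[sex][f.disease_id] = "proportional hazards violated (FDR)"
            else:
                ph_ok.append(f)
        stage["ph_test"] = len(ph_ok)

        counts[sex] = stage
        survivors[sex] = {f.disease_id for f in ph_ok}

    included = sorted(survivors["male"] & survivors["female"])
    for sex in ("male", "female"):
        for d in sorted(survivors[sex] - set(included)):
            reasons[sex][d] = "not selected in both sexes"
        counts[sex]["unisex"] = len(included)
    return SelectionReport(stage_counts=counts, exclusion_reasons=reasons, included=included)
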