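"""Comparisons between diseases in fitted-parameter space.

Maximum-likelihood estimates are asymptotically multivariate normal, so a
disease in one sex is summarised by a Gaussian N(mu, Sigma) over its fitted
log hazard ratios.  Everything here operates on that Gaussian view:
marginalisation to a comparison subset, chi-square equality tests between
diseases (or between the sexes for one disease), the Bhattacharyya distance
between fits, nearest-partner identification, and a within-cluster
homogeneity test whose statistic is the sum of pairwise equality statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .covariates import COMPARISON_COVARIATES
from .cox import DiseaseFit

#: relative condition-number guard for covariance solves
_COND_GUARD = 1e12


@dataclass
class MarginalFit:
    """Comparison-subset Gaussian of a fitted disease: N(mu, sigma)."""

    disease_id: str
    sex: str
    mu: np.ndarray
    sigma: np.ndarray
    subset_names: list[str]


@dataclass
class PairTest:
    """Chi-square equality test between two Gaussian fits."""

    id_a: tuple[str, str]
    id_b: tuple[str, str]
    chi2_stat: float
    dof: int
    p_value: float
    fdr_q: Optional[float] = None


@dataclass
class HomogeneityResult:
    """Within-cluster equality test over a full cluster assignment."""

    statistic: float
    dof: int
    p_value: float
    n_groups: int
    group_sizes: list[int]


def marginalise(fit: DiseaseFit, subset_names: Optional[Sequence[str]] = None) -> MarginalFit:
    """Extract the comparison-subset Gaussian from a full fit.

    The subset mean and covariance are simply the corresponding rows and
    columns of the parent estimates — no refitting.  Defaults to the six
    strong contrasts: BMI, height, SBP, slow walking, regular drinking,
    current smoking.
    """
    if not fit.ok:
        raise ValueError(f"cannot marginalise failed fit {fit.disease_id}/{fit.sex}")
    if subset_names is None:
        subset_names = COMPARISON_COVARIATES
    unknown = [n for n in subset_names if n not in fit.covariate_names]
    if unknown:
        raise KeyError(
            f"unknown covariates {unknown}; valid names: {fit.covariate_names}"
        )
    idx = [fit.covariate_names.index(n) for n in subset_names]
    return MarginalFit(
        disease_id=fit.disease_id,
        sex=fit.sex,
        mu=fit.mu_hat[idx].copy(),
        sigma=fit.sigma_hat[np.ix_(idx, idx)].copy(),
        subset_names=list(subset_names),
    )


def _guarded_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Symmetric solve with a condition-number guard."""
    w = np.linalg.eigvalsh(A)
    if w[0] <= 0 or w[-1] / w[0] > _COND_GUARD:
        raise np.linalg.LinAlgError("ill-conditioned or singular covariance sum")
    return np.linalg.solve(A, b)


def equality_stat(a: MarginalFit, b: MarginalFit) -> float:
    """(mu1-mu2)' (Sigma1+Sigma2)^{-1} (mu1-mu2)."""
    if a.subset_names != b.subset_names:
        raise ValueError("subset_names mismatch")
    d = a.mu - b.mu
    return float(d @ _guarded_solve(a.sigma + b.sigma, d))


def equality_test(a: MarginalFit, b: MarginalFit) -> PairTest:
    """Test the null that two fits share the same true parameter vector.

    Under the null, mu1_hat - mu2_hat ~ N(0, Sigma1+Sigma2), so the quadratic
    form is chi-square with one degree of freedom per parameter.
    """
    stat = equality_stat(a, b)
    dof = len(a.mu)
    return PairTest(
        id_a=(a.disease_id, a.sex),
        id_b=(b.disease_id, b.sex),
        chi2_stat=stat,
        dof=dof,
        p_value=float(stats.chi2.sf(stat, dof)),
    )


def sex_difference_scan(
    fits: Sequence[DiseaseFit],
    subset_names: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Male-vs-female equality test for every disease fitted in both sexes.

    Returns one row per disease with the chi-square statistic, p-value and
    Benjamini-Hochberg q-value over the scan family; ``flagged`` marks
    diseases significant at ``alpha`` after the FDR adjustment.
    """
    by_id: dict[str, dict[str, DiseaseFit]] = {}
    for f in fits:
        if f.ok:
            by_id.setdefault(f.disease_id, {})[f.sex] = f
    rows = []
    for d in sorted(by_id):
        pair = by_id[d]
        if "male" not in pair or "female" not in pair:
            continue
        t = equality_test(
            marginalise(pair["male"], subset_names),
            marginalise(pair["female"], subset_names),
        )
        rows.append({"disease_id": d, "chi2_stat": t.chi2_stat, "dof": t.dof,
                     "p_value": t.p_value})
    table = pd.DataFrame(rows)
    if len(table):
        reject, q, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["fdr_q"] = q
        table["flagged"] = reject
    else:
        table["fdr_q"] = []
        table["flagged"] = []
    return table


def bhattacharyya_distance(a: MarginalFit, b: MarginalFit) -> float:
    """Bhattacharyya distance between two Gaussian fits.

    D_B = (1/8) (mu1-mu2)' Sigma^{-1} (mu1-mu2)
        + (1/2) log( det Sigma / sqrt(det Sigma1 det Sigma2) ),
    with Sigma = (Sigma1 + Sigma2)/2: the negative log of the overlap
    integral of the two densities.  The quadratic term shrinks when the same
    mean difference comes with larger uncertainty; the log-determinant term
    compares the covariance shapes.
    """
    if a.subset_names != b.subset_names:
        raise ValueError("subset_names mismatch")
    for s in (a.sigma, b.sigma):
        if np.linalg.eigvalsh(s)[0] <= 0:
            raise ValueError("covariance not positive definite")
    pooled = (a.sigma + b.sigma) / 2.0
    d = a.mu - b.mu
    quad = float(d @ _guarded_solve(pooled, d)) / 8.0
    s, ld_pooled = np.linalg.slogdet(pooled)
    _, ld_a = np.linalg.slogdet(a.sigma)
    _, ld_b = np.linalg.slogdet(b.sigma)
    return quad + 0.5 * (ld_pooled - 0.5 * (ld_a + ld_b))


def distance_matrix(marginals: Sequence[MarginalFit]) -> pd.DataFrame:
    """Symmetric Bhattacharyya distance matrix over disease-sex entries.

    Rows/columns are labelled ``"<disease_id>|<sex>"``.
    """
    labels = [f"{m.disease_id}|{m.sex}" for m in marginals]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate disease-sex entries")
    n = len(marginals)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bhattacharyya_distance(marginals[i], marginals[j])
    if (D < 0).any():
        raise AssertionError("negative Bhattacharyya distance")
    return pd.DataFrame(D, index=labels, columns=labels)


def split_label(label: str) -> tuple[str, str]:
    disease_id, sex = label.rsplit("|", 1)
    return disease_id, sex


def identify_partners(dm: pd.DataFrame) -> pd.DataFrame:
    """Nearest partner and opposite-sex-counterpart rank for every entry.

    For each disease-sex entry: the nearest other entry by distance, and the
    rank (ascending distance over all other entries; ties share the minimum
    rank) of the same disease in the opposite sex.  Entries without an
    opposite-sex counterpart get rank NaN.
    """
    labels = list(dm.index)
    D = dm.to_numpy()
    if len(labels) < 2:
        return pd.DataFrame(
            columns=["disease_id", "sex", "nearest", "nearest_distance",
                     "counterpart_rank"],
        ).rename_axis("entry")
    rows = []
    for i, lab in enumerate(labels):
        disease, sex = split_label(lab)
        other_sex = "female" if sex == "male" else "male"
        counterpart = f"{disease}|{other_sex}"
        d = np.delete(D[i], i)
        others = labels[:i] + labels[i + 1:]
        j_near = int(np.argmin(d))
        if counterpart in others:
            dc = d[others.index(counterpart)]
            rank = int(1 + np.sum(d < dc))  # ties share the minimum rank
        else:
            rank = np.nan
        rows.append({
            "entry": lab, "disease_id": disease, "sex": sex,
            "nearest": others[j_near], "nearest_distance": float(d[j_near]),
            "counterpart_rank": rank,
        })
    return pd.DataFrame(rows).set_index("entry")


def identification_summary(partners: pd.DataFrame, k: Optional[int] = None) -> dict:
    """Fraction of entries whose counterpart is nearest (and within rank k).

    ``k`` defaults to 5% of the candidate pool, mirroring a 'nearest 5%'
    summary.
    """
    ranks = partners["counterpart_rank"].dropna()
    n_others = len(partners) - 1
    if k is None:
        k = max(1, round(0.05 * n_others))
    return {
        "n_entries": int(len(partners)),
        "n_with_counterpart": int(len(ranks)),
        "top1_fraction": float((ranks == 1).mean()) if len(ranks) else np.nan,
        "k": int(k),
        "topk_fraction": float((ranks <= k).mean()) if len(ranks) else np.nan,
    }


def cluster_homogeneity(
    marginals: Sequence[MarginalFit],
    assignment: dict[str, str] | dict[tuple[str, str], str],
    labels: Optional[Sequence[str]] = None,
) -> HomogeneityResult:
    """Test that diseases within each cluster share a common mean.

    The statistic sums the pairwise chi-square equality statistics over all
    unordered within-cluster pairs and is referred to chi-square with
    p * sum_g n_g(n_g-1)/2 degrees of freedom (p = parameter count, n_g the
    cluster sizes).  For clusters of more than two members the pairwise
    differences share MLEs, so the chi-square reference is an approximation
    that is exact in mean but slightly wide in spread; for pair clusters it
    is exact.
    """
    if labels is None:
        labels = [f"{m.disease_id}|{m.sex}" for m in marginals]
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab not in assignment:
            raise KeyError(f"entry {lab} has no cluster assignment")
        groups.setdefault(str(assignment[lab]), []).append(i)
    p_dim = len(marginals[0].subset_names)
    stat = 0.0
    dof = 0
    for g, members in groups.items():
        n_g = len(members)
        dof += p_dim * (n_g * (n_g - 1)) // 2
        for a in range(n_g):
            for b in range(a + 1, n_g):
                try:
                    stat += equality_stat(marginals[members[a]], marginals[members[b]])
                except np.linalg.LinAlgError as e:
                    raise np.linalg.LinAlgError(
                        f"singular covariance sum for pair "
                        f"({labels[members[a]]}, {labels[members[b]]})"
                    ) from e
    p_value = float(stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return HomogeneityResult(
        statistic=stat, dof=dof, p_value=p_value,
        n_groups=len(groups), group_sizes=sorted(len(m) for m in groups.values()),
    )


def pairwise_equality_matrix(marginals: Sequence[MarginalFit]) -> np.ndarray:
    """Matrix of pairwise equality statistics (used to scan cluster cuts)."""
    n = len(marginals)
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            Q[i, j] = Q[j, i] = equality_stat(marginals[i], marginals[j])
    return Q
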