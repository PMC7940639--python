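"""Hierarchical clustering of diseases on the Bhattacharyya distance matrix.

Agglomeration uses the Ward.D2 update rule applied directly to the supplied
(non-Euclidean) distances — the same convention as R's ``hclust`` with
``method="ward.D2"``; the theoretical caveat that Ward's criterion assumes
Euclidean distances is accepted and documented.  Cluster-count selection
evaluates the within-cluster homogeneity statistic at every cut and picks the
elbow by the maximum perpendicular distance to the chord joining the curve's
endpoints.  A pair-overlap statistic p_AB quantifies agreement between two
clusterings of the same entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.special import expit
from scipy.stats import chi2

from .paramspace import MarginalFit, cluster_homogeneity, pairwise_equality_matrix


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    entry_labels: list[str]
    elbow_curve: pd.DataFrame  # columns: n_clusters, statistic, dof, p_value
    selected_k: int
    min_nonsignificant_k: Optional[int]
    labels_at_selected_k: dict[str, int] = field(default_factory=dict)

    def labels_at(self, k: int) -> dict[str, int]:
        flat = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.entry_labels, (int(c) for c in flat)))


@dataclass
class StabilityComparison:
    n_a: int
    n_b: int
    n_ab: int
    p_ab: float
    sensitive_entries: list[str]


def hierarchical_cluster(dm: pd.DataFrame) -> np.ndarray:
    """Ward.D2 linkage from a labelled symmetric distance matrix."""
    D = dm.to_numpy(float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any() or (D < 0).any():
        raise ValueError("distances must be non-negative and finite")
    return linkage(squareform(D, checks=False), method="ward")


def elbow_index(values: Sequence[float], scale: str = "log") -> int:
    """0-based index of the elbow of a decreasing curve.

    Both axes are scaled to [0, 1]; the elbow is the point with maximum
    perpendicular distance to the chord joining the first and last points.
    By default the statistic axis is taken on a log scale (zeros clamped a
    decade below the smallest positive value): homogeneity curves fall over
    several orders of magnitude when cluster separation is strong, and a
    linear chord would place the elbow inside the steep initial descent
    rather than at the corner where the curve flattens.  ``scale="linear"``
    applies the chord rule to the raw values.
    """
    y = np.asarray(values, float)
    if len(y) < 3:
        return 0
    if scale == "log":
        pos = y[y > 0]
        floor = pos.min() / 10.0 if len(pos) else 1e-300
        y = np.log10(np.maximum(y, floor))
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    x = np.linspace(0.0, 1.0, len(y))
    span = y[0] - y[-1]
    yn = (y - y[-1]) / span if span != 0 else np.zeros_like(y)
    # distance from (x, yn) to the chord from (0, yn[0]) to (1, yn[-1])
    p0 = np.array([0.0, yn[0]])
    p1 = np.array([1.0, yn[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.stack([x, yn], axis=1) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return int(np.argmax(dist))


def select_k(
    Z: np.ndarray,
    marginals: Sequence[MarginalFit],
    k_range: Optional[Sequence[int]] = None,
    alpha: float = 0.05,
    override_k: Optional[int] = None,
    elbow_scale: str = "log",
) -> ClusteringResult:
    """Evaluate homogeneity along tree cuts and pick the cluster count.

    For each candidate N the tree is cut into N clusters and the
    within-cluster chi-square homogeneity statistic evaluated; ``selected_k``
    is the elbow of that curve (or ``override_k``).  Also reports the
    smallest N whose homogeneity p-value exceeds ``alpha``.
    """
    labels = [f"{m.disease_id}|{m.sex}" for m in marginals]
    n = len(labels)
    if k_range is None:
        k_range = range(1, n + 1)
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[0] < 1 or k_range[-1] > n:
        raise ValueError(f"k_range must lie within [1, {n}]")

    p_dim = len(marginals[0].subset_names)
    Q = pairwise_equality_matrix(marginals)
    rows = []
    for k in k_range:
        flat = fcluster(Z, t=k, criterion="maxclust")
        stat, dof = 0.0, 0
        for c in np.unique(flat):
            members = np.flatnonzero(flat == c)
            n_g = len(members)
            dof += p_dim * (n_g * (n_g - 1)) // 2
            if n_g > 1:
                stat += float(Q[np.ix_(members, members)].sum()) / 2.0
        p = float(chi2.sf(stat, dof)) if dof > 0 else 1.0
        rows.append({"n_clusters": k, "statistic": stat, "dof": dof, "p_value": p})
    curve = pd.DataFrame(rows)

    selected = (override_k if override_k is not None
                else k_range[elbow_index(curve["statistic"], scale=elbow_scale)])
    nonsig = curve.loc[curve["p_value"] > alpha, "n_clusters"]
    min_nonsig = int(nonsig.min()) if len(nonsig) else None

    result = ClusteringResult(
        linkage_matrix=Z,
        entry_labels=labels,
        elbow_curve=curve,
        selected_k=int(selected),
        min_nonsignificant_k=min_nonsig,
    )
    result.labels_at_selected_k = result.labels_at(result.selected_k)
    return result


def heatmap_values(
    marginals: Sequence[MarginalFit], subset_names: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Inverse-logit map of marginal coefficients onto [0, 1].

    0.5 is neutral, above 0.5 an association with higher risk.
    """
    if subset_names is None:
        subset_names = marginals[0].subset_names
    rows = {}
    for m in marginals:
        idx = [m.subset_names.index(n) for n in subset_names]
        rows[f"{m.disease_id}|{m.sex}"] = expit(m.mu[idx])
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(subset_names))


def _within_pairs(labels: dict[str, int]) -> set[frozenset]:
    groups: dict[int, list[str]] = {}
    for e, c in labels.items():
        groups.setdefault(c, []).append(e)
    pairs = set()
    for members in groups.values():
        pairs.update(frozenset(p) for p in combinations(sorted(members), 2))
    return pairs


def compare_clusterings(a: dict[str, int], b: dict[str, int]) -> StabilityComparison:
    """Pair-overlap stability between two clusterings of the same entries.

    p_AB = n_AB / min(n_A, n_B), with n_A/n_B the within-cluster unordered
    pair counts and n_AB the pairs common to both.  Entries with no partner
    co-clustered with them in both A and B are reported as sensitive.  When
    one clustering has no within-cluster pairs at all, p_AB is 1 if both are
    pair-free and 0 otherwise.
    """
    if set(a) != set(b):
        raise ValueError("clusterings must cover the same entry set")
    pa, pb = _within_pairs(a), _within_pairs(b)
    common = pa & pb
    lo = min(len(pa), len(pb))
    if lo == 0:
        p_ab = 1.0 if len(pa) == len(pb) else 0.0
    else:
        p_ab = len(common) / lo
    partnered = {e for pair in common for e in pair}
    sensitive = sorted(set(a) - partnered)
    return StabilityComparison(
        n_a=len(pa), n_b=len(pb), n_ab=len(common), p_ab=p_ab,
        sensitive_entries=sensitive,
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick export of the dendrogram with merge heights as branch lengths."""
    root = to_tree(Z)
    safe = [str(l).replace(" ", "_").replace(",", "_").replace("(", "_").replace(")", "_")
            for l in labels]

    def render(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{safe[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(root, root.dist) + ";"
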