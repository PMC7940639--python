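# Methods

## The model

Disease incidence is modelled per disease and per sex with a Cox
proportional-hazards model on the attained-age timescale:
λ(t | x) = λ₀(t) exp(βᵀx), where t is age in years and x the participant's
covariate vector. Participants enter the risk set at their study entry age
(delayed entry / left truncation) and leave at their first event for the
disease under study, at the administrative end of follow-up, or at a first
cancer event — cancers and their treatment alter subsequent disease risk, so
follow-up after a cancer is discarded. Fits are stratified by year-of-birth
stratum, letting each stratum carry its own baseline hazard, and adjusted by
entry age (linear). Ties are handled by the Efron approximation (the
simulator produces continuous ages, so ties are rare). Women's models
additionally include HRT use and parity.

Covariates and baselines: standardised BMI, height, and systolic blood
pressure (standardised with the *joint* mean/SD across sexes, so male and
female coefficients share a scale); smoking never/previous/current (baseline
never); alcohol rarely/sometimes/regularly (baseline rarely); walking pace
slow/average/brisk (baseline brisk); diabetes; education in three levels
(baseline degree); deprivation tertile (baseline lowest); and for women HRT
and having had children. An alternative "tertile" coding replaces each
continuous factor with sex-specific tertile indicators; the top-vs-bottom
contrast then plays the continuous coefficient's role in comparisons.

## Selection cascade

A disease enters the comparison set only if, in order:

1. the fit converges with a positive-definite covariance and **≥ 50 cases**;
2. its covariance eigenvalues are not outlying: the log of its largest
   (smallest) eigenvalue lies within 2.5 across-disease SDs above (below)
   the across-disease mean, computed with outliers included. Log scale is
   used because eigenvalues are positive and vary over orders of magnitude;
   both extremes are screened separately;
3. the multivariate significance statistic μ̂ᵀΣ⁻¹μ̂ ~ χ²(p) is significant at
   0.05 after a Bonferroni adjustment over the diseases tested in that sex;
4. the global Schoenfeld proportional-hazards test is *not* rejected at 0.05
   after a Benjamini–Hochberg FDR adjustment (FDR is the stricter choice
   when testing for failure: it excludes more diseases than Bonferroni);
5. the disease survives in both sexes ("unisex" requirement).

The Schoenfeld test is the global Grambsch–Therneau statistic: with
Schoenfeld residuals S (one row per event) and centred event ages g,
u = Sᵀg and d/(Σg²)·uᵀΣu ~ χ²(p), using the identity time transform.
Residuals are computed directly under delayed entry (risk set
{entry < t ≤ exit} per stratum) since standard fitters do not expose them
with left truncation; the implementation is calibrated against simulation
(uniform null p-values) and detects a planted sign-flipping effect.

## Comparisons between fits

MLEs are treated as Gaussian: disease d in sex s is N(μ̂, Σ). A parameter
subset is obtained by marginalisation — the corresponding rows/columns of μ̂
and Σ, *not* a refit. The default comparison subset is the six strong
contrasts (BMI, height, SBP, slow walking, regular drinking, current
smoking): one variable per risk factor, so no factor dominates the distance
by its number of levels, and each contrast is a biologically large one.

Equality of two fits is tested with
(μ̂₁−μ̂₂)ᵀ(Σ₁+Σ₂)⁻¹(μ̂₁−μ̂₂) ~ χ²(p). The male-vs-female scan applies this per
disease with BH q-values over the scan family, optionally with BMI removed
from the subset (the rerun used to show how much of the sex difference is
BMI-driven).

The within-cluster homogeneity statistic sums the pairwise equality
statistics over unordered within-cluster pairs and is referred to
χ²(p·Σ_g n_g(n_g−1)/2). **Caveat**: for clusters of more than two members
the pairwise differences share MLEs and are dependent; the χ² reference is
then an approximation that is exact in mean but somewhat narrow in spread
(at p=6 and cluster sizes {2,3}: simulated mean 24.0 as predicted, variance
≈ 68 vs the χ²₍₂₄₎ value of 48). For pair clusters it is exact, and the test
suite calibrates it in that regime. In practice the statistic is used as a
descriptive curve across tree cuts, where the approximation is immaterial
for locating the elbow.

## Bhattacharyya distance and identification

D_B = ⅛ ΔᵀΣ̄⁻¹Δ + ½ log(det Σ̄ / √(det Σ₁ det Σ₂)), Σ̄ = (Σ₁+Σ₂)/2, Δ = μ₁−μ₂:
the negative log overlap of the two Gaussians. When Σ₁ = Σ₂ the second term
vanishes and D_B equals the equality χ² statistic divided by 4 (asserted to
1e-10 in tests); the Hellinger distance is the related √(1−exp(−D_B)).
Uncertain estimates are pulled together (larger covariances shrink the first
term), which is the point of using D_B rather than a plain Euclidean
distance on coefficients.

Each disease-sex entry's *partner* is its nearest other entry by D_B; the
candidate pool is all other included entries of both sexes (so a rank of 1
means the nearest of all ~2m−1 entries is the same disease in the opposite
sex). Ties share the minimum rank — conservative for "rank ≤ k" summaries.
Matrix solves go through a symmetric eigendecomposition guard rejecting
condition numbers above 1e12; the eigenvalue screen upstream should make
such failures a signal rather than noise.

## Clustering and cluster count

Ward.D2 agglomeration is applied directly to the (non-Euclidean) D_B matrix
— the same convention as R's `hclust(method="ward.D2")`, and scipy's `ward`
linkage reproduces it exactly on a shared fixture. Ward's criterion formally
assumes Euclidean distances; as with the original analyses this caveat is
accepted and documented rather than worked around.

The cluster count is chosen by an elbow rule on the homogeneity statistic
evaluated at every tree cut in the scanned range: the cut with maximum
perpendicular distance to the chord joining the curve's endpoints, with both
axes normalised to [0,1] and the statistic axis taken on a log₁₀ scale
(zeros clamped a decade below the smallest positive value). The log scale is
deliberate: under strong separation the curve falls over several orders of
magnitude and a linear chord lands in the initial descent rather than at the
corner where the curve flattens; on a log axis the rule recovers planted
cluster counts and still returns N=2 on the textbook curve {10, 2, 1.9,
1.8, ...}. The scale, the scanned range and a manual override are all
exposed. The smallest cut whose homogeneity p-value exceeds 0.05 is reported
alongside (the "no remaining within-cluster differences" count).

Heat-map values are the inverse logit 1/(1+e^(−β)) of the marginal
coefficients: 0.5 neutral, above 0.5 higher risk.

## Stability metric

For clusterings A and B of the same entries, n_A and n_B count within-cluster
unordered pairs, n_AB the pairs common to both, and p_AB = n_AB/min(n_A,n_B).
Entries with no partner co-clustered with them in both A and B are reported
as "sensitive". Degenerate case (not fixed by the definition): when
min(n_A,n_B)=0, p_AB is taken as 1 if both clusterings are pair-free and 0
otherwise. The pipeline's sensitivity reruns recompute the fits (excluding
participants with prior same-cluster diseases, or recoding continuous
factors as tertiles), recluster at the same cut, and report p_AB against the
main run.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- Two sexes; entry ages uniform on 40–69; a nominal entry year of 2008 fixes
  year of birth; equal-occupancy YOB strata (3 by default — the encoding of
  YOB stratification is not fixed by the design, so the count is a config
  choice); administrative follow-up of 10 years.
- Continuous factors drawn per sex with realistic means/SDs (e.g. heights
  175.6±6.8 / 162.4±6.3 cm) then jointly standardised; categorical factors
  drawn per sex with plausible UK-cohort-like level probabilities; HRT and
  parity generated for women only and structurally absent from male designs.
- Disease event ages drawn exactly by inverse-transform sampling from the
  proportional-hazards model: per-participant hazard
  r_stratum · exp(βᵀx), constant in age within a stratum (piecewise-constant
  baseline across strata, rising 0.8→1.2 by default so stratification is
  non-trivial). Events at or before entry are recorded as *prevalent* and
  flagged; prevalent cases of a disease are excluded from its own risk set
  (incident analysis) and feed the prior-disease sensitivity option.
- An independent exponential "cancer" clock starting at entry censors all
  later events; administrative censoring applies at entry + follow-up.
- Planted structure: cluster centres on the six comparison contrasts drawn
  from N(0, 0.45²) per coordinate and redrawn until all pairwise centre
  separations exceed 0.5; per-disease within-cluster jitter SD 0.03; weaker
  secondary contrasts (previous smoking, occasional drinking, average pace)
  at 0.4× their strong counterparts; small random adjustment-covariate
  effects. A configurable fraction of diseases (≈8% by default) carries a
  ±0.3 female-vs-male BMI shift, the planted analogue of sex-specific BMI
  associations.
- Default study conditions: 100 diseases in 12 clusters, 50 000
  participants, baseline rate 0.002/year — sized so every disease clears the
  50-case floor. All parameters are exposed in `SimulationConfig`.

What the generator does *not* emulate: real marginal distributions or
correlations of UK-cohort covariates, ICD-coded disease frequencies,
hospital coding behaviour, non-proportional hazards, or informative
censoring. Passing tests therefore demonstrate that the machinery recovers
truth *when the model is correctly specified*, not that real data satisfy
the model.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the same machinery at reduced
scale, chosen to keep the full suite in the minutes range while preserving
the conditions each check needs: coverage replicates use a single-disease,
high-incidence design (baseline 0.03/year, 60 000 participants, ~1100 male
cases — the heavy left truncation is handled exactly by delayed entry);
identification uses 8 diseases with per-disease profile separation at least
5× the median parameter SE (the regime in which perfect top-1 identification
is the correct answer); cluster recovery uses 8 diseases in 3 clusters with
centre separations ≥1.2; the sex-difference scan uses ≈2000 cases per sex,
where a 0.3 BMI shift is detectable with high power. Each test asserts its
own preconditions (case counts, separation/SE ratios) rather than assuming
them.

## Numerical choices and degenerate inputs

- Covariance solves: symmetric eigendecomposition with a 1e12 condition
  guard; singular sums raise errors naming the offending pair.
- Positive-definiteness of fitted covariances is checked by Cholesky;
  failures are recorded as fit failures, not propagated.
- Bhattacharyya distances are asserted non-negative when assembling a
  distance matrix.
- Empty survivor sets are legal: the pipeline emits a report with the
  selection cascade and null comparison sections.
- Determinism: every stochastic step flows from a single integer seed
  through numpy `SeedSequence`; equal seed and config give byte-identical
  cohorts, event tables and run reports.

## Known limitations

- The χ² reference of the homogeneity test is approximate for clusters
  larger than two (see above).
- Ward.D2 on non-Euclidean D_B has no variance-minimisation guarantee.
- The competing-risk treatment of cancer is censoring only; no cumulative
  incidence or cause-specific decomposition.
- The prior-disease exclusion drops participants at the participant level
  using events before their exit time for the analysed disease; it does not
  model time-varying exposure to prior disease.
- The elbow rule, like all cluster-count heuristics, is a descriptive
  choice; the manual override exists precisely because no established method
  fixes the number of clusters.
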