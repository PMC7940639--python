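"""Tests of the Gaussian-parameter-space machinery: marginalisation, equality
tests, Bhattacharyya distances, partner identification, cluster homogeneity."""

import numpy as np
import pytest
from scipy import integrate, stats

from riskclust.cox import DiseaseFit
from riskclust.paramspace import (
    MarginalFit,
    bhattacharyya_distance,
    cluster_homogeneity,
    distance_matrix,
    equality_stat,
    equality_test,
    identification_summary,
    identify_partners,
    marginalise,
    sex_difference_scan,
)


def gaussian_fit(disease, sex, mu, sigma, names=None):
    mu = np.atleast_1d(np.asarray(mu, float))
    sigma = np.atleast_2d(np.asarray(sigma, float))
    names = names or [f"x{i}" for i in range(len(mu))]
    return MarginalFit(disease, sex, mu, sigma, list(names))


def full_fit(mu, sigma, names, disease="d", sex="male"):
    return DiseaseFit(disease, sex, 500, mu_hat=np.asarray(mu, float),
                      sigma_hat=np.asarray(sigma, float),
                      covariate_names=list(names), ok=True)


def bhattacharyya_1d_by_integration(m1, s1, m2, s2):
    """Independent oracle: -log of the overlap integral of two normal pdfs."""
    f = lambda x: np.sqrt(stats.norm.pdf(x, m1, s1) * stats.norm.pdf(x, m2, s2))
    val, _ = integrate.quad(f, -40, 40, limit=400)
    return -np.log(val)


class TestMarginalise:
    def test_full_subset_is_identity(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        fit = full_fit(rng.normal(size=4), A @ A.T + np.eye(4), list("abcd"))
        m = marginalise(fit, list("abcd"))
        np.testing.assert_array_equal(m.mu, fit.mu_hat)
        np.testing.assert_array_equal(m.sigma, fit.sigma_hat)

    def test_single_coordinate(self):
        fit = full_fit([1.0, 2.0], [[4.0, 1.0], [1.0, 9.0]], ["a", "b"])
        m = marginalise(fit, ["a"])
        np.testing.assert_allclose(m.mu, [1.0])
        np.testing.assert_allclose(m.sigma, [[4.0]])

    def test_unknown_name_lists_valid(self):
        fit = full_fit([1.0], [[1.0]], ["a"])
        with pytest.raises(KeyError, match="a"):
            marginalise(fit, ["zzz"])

    def test_matches_empirical_marginal_of_samples(self):
        """Sub-vector/sub-matrix equals the sampling distribution of the
        coordinate of MVN draws."""
        rng = np.random.default_rng(1)
        mu = np.array([0.3, -0.2, 0.1])
        A = rng.normal(size=(3, 3))
        sigma = A @ A.T + np.eye(3)
        fit = full_fit(mu, sigma, ["a", "b", "c"])
        m = marginalise(fit, ["b"])
        draws = rng.multivariate_normal(mu, sigma, size=200_000)[:, 1]
        assert draws.mean() == pytest.approx(m.mu[0], abs=0.02)
        assert draws.var() == pytest.approx(m.sigma[0, 0], rel=0.02)


class TestEqualityTest:
    def test_identical_fits(self):
        f = gaussian_fit("a", "male", [1.0, 2.0], np.eye(2))
        t = equality_test(f, f)
        assert t.chi2_stat == 0 and t.p_value == 1

    def test_one_dimensional_example(self):
        a = gaussian_fit("a", "male", [0.0], [[1.0]])
        b = gaussian_fit("b", "male", [2.0], [[1.0]])
        t = equality_test(a, b)
        assert t.chi2_stat == pytest.approx(2.0)
        assert t.p_value == pytest.approx(stats.chi2.sf(2, 1))
        rng = np.random.default_rng(2)
        z = rng.standard_normal(400_000)
        mc = (z**2 > 2).mean()
        assert abs(t.p_value - mc) < 3 * np.sqrt(mc * (1 - mc) / z.size)

    def test_null_calibration(self):
        """Sampling both MLEs around a common mean gives uniform p-values."""
        rng = np.random.default_rng(3)
        mu = np.array([0.2, -0.4])
        s1 = np.array([[0.05, 0.01], [0.01, 0.08]])
        s2 = np.array([[0.03, -0.005], [-0.005, 0.02]])
        ps = []
        for _ in range(2000):
            a = gaussian_fit("a", "male", rng.multivariate_normal(mu, s1), s1)
            b = gaussian_fit("b", "male", rng.multivariate_normal(mu, s2), s2)
            ps.append(equality_test(a, b).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBhattacharyya:
    def test_identical_distributions_zero(self):
        f = gaussian_fit("a", "male", [0.5, -1.0], [[0.2, 0.05], [0.05, 0.3]])
        assert bhattacharyya_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "m1,s1,m2,s2",
        [(0.0, 1.0, 2.0, 1.0), (0.0, 1.0, 0.0, np.sqrt(3.0)), (0.3, 0.7, -1.1, 1.9)],
    )
    def test_one_dimensional_closed_form_vs_integration(self, m1, s1, m2, s2):
        a = gaussian_fit("a", "male", [m1], [[s1**2]])
        b = gaussian_fit("b", "male", [m2], [[s2**2]])
        oracle = bhattacharyya_1d_by_integration(m1, s1, m2, s2)
        assert bhattacharyya_distance(a, b) == pytest.approx(oracle, abs=1e-6)

    def test_known_values(self):
        a = gaussian_fit("a", "male", [0.0], [[1.0]])
        b = gaussian_fit("b", "male", [2.0], [[1.0]])
        assert bhattacharyya_distance(a, b) == pytest.approx(0.5)
        c = gaussian_fit("c", "male", [0.0], [[3.0]])
        assert bhattacharyya_distance(a, c) == pytest.approx(0.5 * np.log(2 / np.sqrt(3)))

    def test_symmetry_and_equal_covariance_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            d = rng.integers(1, 5)
            A = rng.normal(size=(d, d))
            sigma = A @ A.T + 0.1 * np.eye(d)
            a = gaussian_fit("a", "male", rng.normal(size=d), sigma)
            b = gaussian_fit("b", "male", rng.normal(size=d), sigma.copy())
            db = bhattacharyya_distance(a, b)
            assert db == pytest.approx(bhattacharyya_distance(b, a), abs=1e-12)
            # with equal covariances the log-det term vanishes and
            # D_B = chi2 statistic / 4
            assert db == pytest.approx(equality_stat(a, b) / 4.0, abs=1e-10)

    def test_larger_covariances_shrink_mean_term(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        B = rng.normal(size=(3, 3))
        s1, s2 = A @ A.T + np.eye(3), B @ B.T + np.eye(3)
        mu1, mu2 = rng.normal(size=3), rng.normal(size=3)
        zero = np.zeros(3)

        def quad_term(c):
            a = gaussian_fit("a", "male", mu1, c * s1)
            b = gaussian_fit("b", "male", mu2, c * s2)
            a0 = gaussian_fit("a", "male", zero, c * s1)
            b0 = gaussian_fit("b", "male", zero, c * s2)
            return bhattacharyya_distance(a, b) - bhattacharyya_distance(a0, b0)

        assert quad_term(3.0) < quad_term(1.0)

    def test_non_positive_definite_rejected(self):
        a = gaussian_fit("a", "male", [0.0], [[0.0]])
        b = gaussian_fit("b", "male", [1.0], [[1.0]])
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            bhattacharyya_distance(a, b)


class TestIdentifyPartners:
    def _well_separated(self):
        tight = 1e-4 * np.eye(2)
        return [
            gaussian_fit("d1", "male", [0.0, 0.0], tight),
            gaussian_fit("d1", "female", [0.01, 0.0], tight),
            gaussian_fit("d2", "male", [5.0, 5.0], tight),
            gaussian_fit("d2", "female", [5.0, 5.01], tight),
        ]

    def test_separated_profiles_identify_perfectly(self):
        dm = distance_matrix(self._well_separated())
        partners = identify_partners(dm)
        assert (partners["counterpart_rank"] == 1).all()
        summary = identification_summary(partners, k=1)
        assert summary["top1_fraction"] == 1.0

    def test_rank_invariant_under_relabelling(self):
        marg = self._well_separated()
        dm = distance_matrix(marg)
        perm = [2, 0, 3, 1]
        dmp = dm.iloc[perm, perm]
        a = identify_partners(dm)["counterpart_rank"]
        b = identify_partners(dmp)["counterpart_rank"]
        assert a.sort_index().equals(b.sort_index())

    def test_exchangeable_entries_top1_matches_chance(self):
        """All entries identically distributed: the counterpart is nearest
        with probability 1/(n_entries - 1)."""
        rng = np.random.default_rng(6)
        m, sigma = 6, 0.1 * np.eye(2)
        hits = trials = 0
        for _ in range(400):
            marg = []
            for i in range(m):
                for sex in ("male", "female"):
                    marg.append(gaussian_fit(
                        f"d{i}", sex, rng.multivariate_normal([0, 0], sigma), sigma))
            ranks = identify_partners(distance_matrix(marg))["counterpart_rank"]
            hits += int((ranks == 1).sum())
            trials += len(ranks)
        p_chance = 1.0 / (2 * m - 1)
        se = np.sqrt(p_chance * (1 - p_chance) / trials)
        assert abs(hits / trials - p_chance) < 3 * se

    def test_missing_counterpart_reported(self):
        marg = self._well_separated()[:3]  # d2 female missing
        partners = identify_partners(distance_matrix(marg))
        assert np.isnan(partners.loc["d2|male", "counterpart_rank"])


class TestClusterHomogeneity:
    def test_singletons_zero(self):
        marg = [gaussian_fit(f"d{i}", "male", [float(i)], [[1.0]]) for i in range(4)]
        res = cluster_homogeneity(marg, {f"d{i}|male": str(i) for i in range(4)})
        assert res.statistic == 0 and res.dof == 0 and res.p_value == 1.0

    def test_dof_formula(self):
        """Clusters of sizes 2 and 3 with 6 parameters: dof = 6*(1+3) = 24."""
        rng = np.random.default_rng(7)
        marg = [gaussian_fit(f"d{i}", "male", rng.normal(size=6), np.eye(6))
                for i in range(5)]
        assign = {"d0|male": "A", "d1|male": "A",
                  "d2|male": "B", "d3|male": "B", "d4|male": "B"}
        res = cluster_homogeneity(marg, assign)
        assert res.dof == 24

    def test_statistic_matches_explicit_double_sum(self):
        """Cross-check against a direct 1/2 * sum_g sum_{i,j in C_g} evaluation."""
        rng = np.random.default_rng(8)
        marg, sigmas = [], []
        for i in range(6):
            A = rng.normal(size=(3, 3))
            s = A @ A.T + np.eye(3)
            sigmas.append(s)
            marg.append(gaussian_fit(f"d{i}", "male", rng.normal(size=3), s))
        assign = {f"d{i}|male": ("A" if i < 4 else "B") for i in range(6)}
        res = cluster_homogeneity(marg, assign)
        groups = {"A": range(4), "B": range(4, 6)}
        direct = 0.0
        for members in groups.values():
            for i in members:
                for j in members:
                    d = marg[i].mu - marg[j].mu
                    direct += d @ np.linalg.inv(sigmas[i] + sigmas[j]) @ d
        assert res.statistic == pytest.approx(direct / 2.0, rel=1e-10)

    def test_null_distribution_exact_for_pair_clusters(self):
        """With clusters of two, within-cluster differences are independent
        across clusters and the statistic is exactly chi2(dof)."""
        rng = np.random.default_rng(9)
        p = 2
        n_pairs = 3
        sigmas = {}
        for g in range(n_pairs):
            for i in range(2):
                A = rng.normal(size=(p, p))
                sigmas[(g, i)] = 0.1 * (A @ A.T + np.eye(p))
        means = {g: rng.normal(size=p) for g in range(n_pairs)}
        stats_ = []
        for _ in range(2000):
            marg = [
                gaussian_fit(f"{g}{i}", "male",
                             rng.multivariate_normal(means[g], sigmas[(g, i)]),
                             sigmas[(g, i)])
                for g in range(n_pairs) for i in range(2)
            ]
            assign = {f"{g}{i}|male": g for g in range(n_pairs) for i in range(2)}
            stats_.append(cluster_homogeneity(marg, assign).statistic)
        dof = p * n_pairs
        assert stats.kstest(stats_, "chi2", args=(dof,)).pvalue > 0.01

    def test_null_mean_matches_dof_for_larger_clusters(self):
        """For clusters of three the pairwise terms are dependent, so the
        chi-square reference is approximate — but its mean still equals the
        degrees of freedom."""
        rng = np.random.default_rng(19)
        p = 2
        sigma = 0.1 * np.eye(p)
        mean = rng.normal(size=p)
        stats_ = []
        for _ in range(3000):
            marg = [gaussian_fit(f"m{i}", "male",
                                 rng.multivariate_normal(mean, sigma), sigma)
                    for i in range(3)]
            assign = {f"m{i}|male": "A" for i in range(3)}
            stats_.append(cluster_homogeneity(marg, assign).statistic)
        dof = p * 3  # 3 within-cluster pairs
        se = np.std(stats_) / np.sqrt(len(stats_))
        assert abs(np.mean(stats_) - dof) < 4 * se


class TestSexDifferenceScan:
    def test_planted_bmi_shift_recovered(self, separated_setup):
        cfg, _, _, fits = separated_setup
        scan = sex_difference_scan(fits)
        planted = {p.disease_id for p in cfg.disease_profiles if p.sex_specific}
        flagged = set(scan.loc[scan["flagged"], "disease_id"])
        sensitivity = len(planted & flagged) / len(planted)
        assert sensitivity >= 0.8
        # an occasional FDR false positive among the null diseases is expected
        assert len(flagged - planted) <= 1

    def test_no_bmi_subset_clears_bmi_only_differences(self, separated_setup):
        cfg, _, _, fits = separated_setup
        from riskclust.covariates import comparison_subset

        scan = sex_difference_scan(fits, comparison_subset("linear", include_bmi=False))
        planted = {p.disease_id for p in cfg.disease_profiles if p.sex_specific}
        flagged = set(scan.loc[scan["flagged"], "disease_id"])
        assert not (flagged & planted)

    def test_null_false_positive_rate(self):
        """Sex-identical Gaussian fits: flagged fraction stays near zero."""
        rng = np.random.default_rng(10)
        fits = []
        for i in range(40):
            mu = rng.normal(size=3)
            s = 0.05 * np.eye(3)
            for sex in ("male", "female"):
                fits.append(full_fit(rng.multivariate_normal(mu, s), s,
                                     ["a", "b", "c"], disease=f"d{i}", sex=sex))
        scan = sex_difference_scan(fits, ["a", "b", "c"])
        assert scan["flagged"].mean() <= 0.05
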