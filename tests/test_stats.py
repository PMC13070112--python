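import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from petcohort.stats import (
    PowerSpec,
    RankDeficientError,
    bonferroni_adjust,
    describe,
    group_compare,
    hierarchical_regression,
    log_lesion_transform,
    mahalanobis_outliers,
    partial_correlation,
    pearson_correlation,
    power_at_n,
    power_min_n,
    univariate_outliers,
)
from petcohort.synthetic import CohortSpec, generate_cohort, lognormal_params


class TestUnivariateOutliers:
    def test_printed_lesion_worked_example(self):
        # printed summary: mean 2.0 ml, SD 2.9 ml, range 0.1-14.7 ml
        report = univariate_outliers(
            [0.1, 14.7], threshold_sd=3.29, center=2.0, scale=2.9
        )
        assert report.n_flagged == 1
        assert report.flagged_ids == [1]
        assert report.statistics[1] == pytest.approx((14.7 - 2.0) / 2.9, rel=1e-9)
        assert report.statistics[1] == pytest.approx(4.38, abs=0.01)

    def test_constant_vector_warns_no_flags(self):
        with pytest.warns(UserWarning):
            report = univariate_outliers([3.0, 3.0, 3.0, 3.0])
        assert report.n_flagged == 0

    def test_statistics_use_pre_exclusion_moments(self, rng):
        x = np.concatenate([rng.normal(size=50), [40.0]])
        report = univariate_outliers(x)
        assert report.statistics[-1] == pytest.approx(
            abs(40.0 - x.mean()) / x.std(ddof=1)
        )

    def test_monte_carlo_flag_rate_matches_normal_tail(self):
        # expected flags/cohort = 55 * 2*Phi(-3.29) ~= 0.055
        rng = np.random.default_rng(11)
        counts = [
            univariate_outliers(rng.standard_normal(55)).n_flagged
            for _ in range(1000)
        ]
        assert 0.01 <= np.mean(counts) <= 0.12


class TestMahalanobisOutliers:
    def test_flag_rate_near_nominal(self, rng):
        X = rng.multivariate_normal(
            np.zeros(3), [[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]], size=100_000
        )
        report = mahalanobis_outliers(X, p_threshold=0.001)
        rate = report.n_flagged / 100_000
        assert rate == pytest.approx(0.001, abs=0.0006)

    def test_planted_outlier_flagged(self, rng):
        X = rng.normal(size=(60, 3))
        X[13] = 10.0
        report = mahalanobis_outliers(X)
        assert 13 in report.flagged_ids

    def test_univariate_equivalence_at_p_1(self, rng):
        x = rng.normal(size=500)
        x[7] = 6.0
        thresh = np.sqrt(sps.chi2.ppf(0.999, df=1))  # = 3.2905
        uni = univariate_outliers(x, threshold_sd=thresh)
        # D^2 with ddof=1 covariance equals z^2 with sample SD
        maha = mahalanobis_outliers(x.reshape(-1, 1), p_threshold=0.001)
        assert set(maha.flagged_ids) == set(uni.flagged_ids)
        assert np.allclose(maha.statistics, uni.statistics**2, rtol=1e-9)

    def test_singular_covariance_errors(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError):
            mahalanobis_outliers(X)


class TestLogLesionTransform:
    def test_value_of_one_maps_to_zero(self):
        logged, _ = log_lesion_transform([1.0, 2.0, 3.0, 4.0])
        assert logged[0] == 0.0

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            log_lesion_transform([1.0, 0.0, 2.0])

    def test_lognormal_draws_symmetrize(self, rng):
        mu, sigma = lognormal_params(2.0, 2.9)
        vols = np.exp(rng.normal(mu, sigma, 10_000))
        logged, report = log_lesion_transform(vols)
        # closed-form log-normal skewness (cv + cv^3) with cv = 1.45
        cv = 2.9 / 2.0
        assert report["skewness_before"] > 1.0
        assert report["skewness_before"] == pytest.approx(3 * cv + cv**3, rel=0.5)
        assert abs(report["skewness_after"]) < 0.5


class TestCorrelations:
    def test_partial_matches_closed_form_single_covariate(self, rng):
        n = 400
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + 0.4 * x + rng.normal(size=n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        want = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        got, _ = partial_correlation(x, y, z)
        assert got == pytest.approx(want, abs=1e-10)

    def test_uncorrelated_covariate_leaves_r(self, rng):
        n = 200_000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)
        r0, _ = pearson_correlation(x, y)
        rp, _ = partial_correlation(x, y, z)
        assert rp == pytest.approx(r0, abs=0.01)

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        r, p = partial_correlation(x, x, z)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_p_value_matches_t_reference(self, rng):
        n = 60
        z = rng.normal(size=n)
        x = rng.normal(size=n) + 0.4 * z
        y = rng.normal(size=n) + 0.3 * z
        r, p = partial_correlation(x, y, z)
        df = n - 3
        t = r * np.sqrt(df / (1 - r**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), df), rel=1e-12)


class TestHierarchicalRegression:
    def test_single_predictor_beta_equals_pearson_r(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        res = hierarchical_regression(df, "y", [["x"]])[0]
        r, _ = pearson_correlation(x, y)
        assert res.beta["x"] == pytest.approx(r, abs=1e-12)

    def test_generator_truth_recovery(self, rng):
        n = 10_000
        age = rng.normal(size=n)
        x1 = rng.normal(size=n)
        y = 0.45 * x1 + rng.normal(size=n) * np.sqrt(1 - 0.45**2)
        df = pd.DataFrame({"age": age, "x1": x1, "y": y})
        res = hierarchical_regression(df, "y", [["age"], ["x1"]])
        assert res[1].beta["x1"] == pytest.approx(0.45, abs=0.03)

    def test_delta_r2_f_matches_direct_nested_comparison(self, rng):
        n = 120
        X = rng.normal(size=(n, 3))
        y = X @ [0.3, -0.2, 0.1] + rng.normal(size=n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        res = hierarchical_regression(df, "y", [["a"], ["b", "c"]])
        # independent oracle: direct RSS-based nested F on the same z-data
        Z = df.apply(lambda c: (c - c.mean()) / c.std(ddof=1))
        yv = Z["y"].to_numpy()

        def rss(cols):
            M = np.column_stack([np.ones(n)] + [Z[c].to_numpy() for c in cols])
            return float(
                np.sum((yv - M @ np.linalg.lstsq(M, yv, rcond=None)[0]) ** 2)
            )

        rss_red, rss_full = rss(["a"]), rss(["a", "b", "c"])
        df2 = n - 3 - 1
        f_direct = ((rss_red - rss_full) / 2) / (rss_full / df2)
        assert res[1].f_change == pytest.approx(f_direct, abs=1e-10)
        assert res[1].p_change == pytest.approx(sps.f.sf(f_direct, 2, df2), rel=1e-9)

    def test_partial_r_sign_matches_beta(self, big_cohort):
        t = big_cohort.table.head(500).copy()
        t["sex_male"] = (t.sex == "M").astype(int)
        t["log_les"] = np.log(t.lesion_volume_ml)
        res = hierarchical_regression(
            t, "latent_dat", [["age", "sex_male"], ["log_les"], ["latent_maob"]]
        )
        for block in res:
            assert np.all(np.sign(block.beta) == np.sign(block.partial_r))

    def test_adjusted_r2_below_r2(self, big_cohort):
        t = big_cohort.table.head(200)
        res = hierarchical_regression(t, "latent_dat", [["age"], ["latent_maob"]])
        for block in res:
            assert block.adj_r_squared <= block.r_squared

    def test_table3_style_median_beta_over_replicates(self):
        from petcohort.composites import dat_composite, maob_pca_score
        from petcohort.synthetic import MAOB_PCA_REGIONS

        betas = []
        for rep in range(120):
            t = generate_cohort(
                CohortSpec(n_subjects=55, seed=5000 + rep, simulate_tacs=False)
            ).table
            df = pd.DataFrame(
                {
                    "dat_z": dat_composite(t.bp_nd_true_caudate, t.bp_nd_true_putamen),
                    "maob_factor": maob_pca_score(
                        t[[f"ki_true_{r}" for r in MAOB_PCA_REGIONS]]
                    ).scores,
                    "log_lesion": np.log(t.lesion_volume_ml),
                    "age": t.age,
                    "sex_male": (t.sex == "M").astype(int),
                }
            )
            res = hierarchical_regression(
                df, "dat_z", [["age", "sex_male"], ["log_lesion"], ["maob_factor"]]
            )
            betas.append(res[2].beta["maob_factor"])
        assert np.median(betas) == pytest.approx(0.45, abs=0.08)

    def test_collinear_block_raises(self, rng):
        n = 50
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=n)})
        with pytest.raises(RankDeficientError, match="x2"):
            hierarchical_regression(df, "y", [["x", "x2"]])


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        groups = np.repeat(["a", "b"], 4)
        res = group_compare(vals, groups, kind="t")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 6

    def test_sex_difference_t_scale(self):
        # calibrated male-female DAT gap ~0.62 z at n=27/28 -> t ~ 2.4
        ts = []
        for rep in range(200):
            t = generate_cohort(
                CohortSpec(n_subjects=55, seed=9000 + rep, simulate_tacs=False)
            ).table
            from petcohort.composites import dat_composite

            dat = dat_composite(t.bp_nd_true_caudate, t.bp_nd_true_putamen)
            ts.append(group_compare(dat, t.sex, kind="t").statistic)
        # sign depends on group order (M first in ~half the draws)
        assert np.mean(np.abs(ts)) == pytest.approx(2.4, abs=0.5)

    def test_chi_square_identical_proportions_zero(self):
        vals = ["x"] * 10 + ["y"] * 10 + ["x"] * 10 + ["y"] * 10
        groups = ["g1"] * 20 + ["g2"] * 20
        res = group_compare(vals, groups, kind="chi2")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_ancova_matches_partial_structure(self, rng):
        n = 200
        cov = rng.normal(size=n)
        g = rng.integers(0, 2, size=n)
        y = 0.5 * g + 0.3 * cov + rng.normal(size=n)
        res = group_compare(y, g, covariates=pd.DataFrame({"c": cov}))
        assert res.kind == "ancova"
        assert res.p_value < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], ["a", "a"])


class TestBonferroni:
    def test_scaling(self):
        assert bonferroni_adjust([0.01], family_size=5)[0] == pytest.approx(0.05)

    def test_capped_at_one(self):
        assert bonferroni_adjust([0.5], family_size=10)[0] == 1.0

    def test_family_of_one_is_identity(self):
        assert bonferroni_adjust([0.123], family_size=1)[0] == pytest.approx(0.123)

    def test_default_family_is_input_length(self):
        out = bonferroni_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


class TestPower:
    def test_paper_lower_bound_n55(self):
        spec = PowerSpec(f2=0.15, alpha=0.05, power_target=0.80,
                         n_tested_predictors=1, n_covariates=1)
        assert power_min_n(spec) == 55

    def test_power_monotone_in_n(self):
        spec = PowerSpec()
        powers = [power_at_n(spec, n) for n in range(10, 200, 10)]
        assert np.all(np.diff(powers) > 0)

    def test_huge_effect_approaches_minimal_n(self):
        spec = PowerSpec(f2=1e6)
        assert power_min_n(spec) == spec.n_tested_predictors + spec.n_covariates + 2

    def test_alternative_lambda_convention(self):
        spec = PowerSpec()
        assert power_min_n(spec, lambda_convention="df") == 56

    def test_monte_carlo_power_at_returned_n(self, rng):
        # simulation oracle for the lambda = f2*N convention, which
        # corresponds to a tested predictor whose covariate-residual sum
        # of squares equals N exactly; b = sqrt(f2), sigma = 1
        spec = PowerSpec()
        n = power_min_n(spec)
        b = np.sqrt(spec.f2)
        hits = 0
        reps = 5000
        crit = sps.f.ppf(0.95, 1, n - 3)
        for _ in range(reps):
            c = rng.normal(size=n)
            X0 = np.column_stack([np.ones(n), c])
            x = rng.normal(size=n)
            x -= X0 @ np.linalg.lstsq(X0, x, rcond=None)[0]
            x *= np.sqrt(n / (x @ x))
            y = b * x + rng.normal(size=n)
            X1 = np.column_stack([X0, x])
            r0 = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
            r1 = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
            f = (r0 @ r0 - r1 @ r1) / (r1 @ r1 / (n - 3))
            hits += f > crit
        assert hits / reps == pytest.approx(power_at_n(spec, n), abs=0.02)
        assert hits / reps == pytest.approx(spec.power_target, abs=0.025)


class TestDescribe:
    def test_simple_mean(self):
        assert describe([1.0, 2.0, 3.0, 4.0])["mean"] == 2.5

    def test_standard_normal_large_n(self, rng):
        d = describe(rng.standard_normal(100_000))
        assert abs(d["skewness"]) < 0.05
        assert abs(d["kurtosis"]) < 0.1  # excess convention

    def test_lognormal_positive_skew(self, rng):
        mu, sigma = lognormal_params(2.0, 2.9)
        d = describe(np.exp(rng.normal(mu, sigma, 5000)))
        assert d["skewness"] > 1.0
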