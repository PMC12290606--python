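"""Group statistics: counting, ANCOVA, Bayes-factor t-tests, SVM, FWE maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cvbms import stats


class TestCountSuprathreshold:
    def test_strict_counting(self):
        assert stats.count_suprathreshold([0.0, 2.0, 4.0], 3.0) == 1

    def test_all_below_threshold(self):
        assert stats.count_suprathreshold([-1.0, 0.5], 3.0) == 0

    def test_bayes_factor_scale_conversion(self):
        lbf = stats.bf_to_lbf([1, 3, 20, 150])
        np.testing.assert_allclose(np.round(lbf, 2), [0.0, 1.10, 3.00, 5.01])

    def test_monotone_in_threshold(self, rng):
        lbf = rng.normal(0, 2, 500)
        counts = [stats.count_suprathreshold(lbf, t) for t in (0, 1.1, 3, 5.01)]
        assert counts == sorted(counts, reverse=True)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            stats.count_suprathreshold([1.0, 2.0], 0.0, mask=[True])

    def test_count_table_tidy_layout(self, rng):
        maps = {"s1": {"novelty": rng.normal(0, 2, 100)}}
        tab = stats.voxel_count_table(maps, [0, 3])
        assert list(tab.columns) == ["subject", "contrast", "lbf_threshold", "count"]
        assert len(tab) == 2


class TestAncova:
    def test_two_groups_no_covariates_equals_squared_t(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)])
        df = pd.DataFrame({"count": y, "group": ["a"] * 20 + ["b"] * 25})
        F, dfs, p = stats.ancova_group_effect(df, "count")
        t, pt = sps.ttest_ind(y[:20], y[20:])
        assert F == pytest.approx(t ** 2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_aliased_covariate_rejected(self, rng):
        df = pd.DataFrame({"count": rng.normal(0, 1, 30),
                           "group": ["a", "b"] * 15,
                           "age": np.ones(30), "age2": np.ones(30)})
        with pytest.raises(ValueError, match="aliased"):
            stats.ancova_group_effect(df, "count", covariates=["age", "age2"],
                                      categorical=())

    def test_type_one_error_near_nominal_with_covariates(self, rng):
        """Response independent of group, strong covariate: ~5% rejections."""
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            n = 60
            age = rng.uniform(60, 85, n)
            y = 2.0 * age + rng.normal(0, 5, n)
            df = pd.DataFrame({"count": y, "age": age,
                               "group": rng.choice(["a", "b", "c"], n)})
            _, _, p = stats.ancova_group_effect(df, "count", covariates=["age"],
                                                categorical=())
            rejections += p < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 0.04


class TestJzsTtest:
    def test_identical_samples_favor_null(self):
        res = stats.jzs_ttest(np.arange(10.0), np.arange(10.0))
        assert res.bf01 > 1
        assert abs(res.delta_med) < 1e-6

    def test_large_t_drives_bf01_to_zero(self, rng):
        x1 = rng.normal(0, 1, 30)
        res = stats.jzs_ttest(x1 + 5.0, x1)
        assert res.bf01 < 1e-3
        assert res.delta_med > 1

    def test_bf01_strictly_decreasing_in_t(self):
        bfs = [1.0 / stats._jzs_bf10(t, 12.0, 40, np.sqrt(2) / 2)
               for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert all(a > b for a, b in zip(bfs, bfs[1:]))

    def test_matches_independent_quadrature_grid(self):
        """Fine trapezoid integration in the transformed variable u = g/(1+g)."""
        r = np.sqrt(2) / 2
        for t, n1, n2 in [(-3, 10, 12), (1.5, 21, 128), (2.5, 74, 128), (4, 46, 128)]:
            nu, N = n1 + n2 - 2, n1 * n2 / (n1 + n2)
            u = np.linspace(1e-9, 1 - 1e-9, 200_001)
            g = u / (1 - u)
            logden = -(nu + 1) / 2 * np.log1p(t * t / nu)
            f = (np.exp(-0.5 * np.log1p(N * g)
                        - (nu + 1) / 2 * np.log1p(t * t / ((1 + N * g) * nu))
                        - logden)
                 * sps.invgamma.pdf(g, 0.5, scale=r * r / 2) / (1 - u) ** 2)
            oracle = np.trapezoid(f, u)
            mine = stats._jzs_bf10(t, N, nu, r)
            assert abs(mine - oracle) / oracle < 1e-4

    def test_agrees_with_pingouin(self, rng):
        import pingouin as pg

        x1, x2 = rng.normal(0, 1, 20), rng.normal(0.7, 1, 25)
        res = stats.jzs_ttest(x1, x2)
        bf10 = float(pg.bayesfactor_ttest(res.t, 20, 25, paired=False))
        assert res.bf01 == pytest.approx(1 / bf10, rel=1e-3)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.jzs_ttest([1.0, 1.0], [1.0, 1.0])


class TestSvmClassify:
    def test_chance_level_for_random_labels(self, rng):
        X = rng.normal(0, 1, (40, 4))
        y = np.array(["a", "b"] * 20)
        res = stats.svm_classify(X, y, k_folds=5, n_subsamples=40, seed=0)
        assert abs(res.balanced_accuracy - 0.5) < 0.1

    def test_separable_classes_near_perfect(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 3)), rng.normal(4, 0.3, (20, 3))])
        y = np.repeat(["a", "b"], 20)
        res = stats.svm_classify(X, y, k_folds=5, n_subsamples=20, seed=0)
        assert res.balanced_accuracy > 0.95

    def test_reproducible_under_seed(self, rng):
        X = rng.normal(0, 1, (30, 4))
        y = np.repeat(["a", "b"], 15)
        a = stats.svm_classify(X, y, k_folds=3, n_subsamples=10, seed=5)
        b = stats.svm_classify(X, y, k_folds=3, n_subsamples=10, seed=5)
        assert a.balanced_accuracy == b.balanced_accuracy

    def test_small_class_rejected(self, rng):
        X = rng.normal(0, 1, (12, 2))
        y = np.array(["a"] * 10 + ["b"] * 2)
        with pytest.raises(ValueError, match="k_folds"):
            stats.svm_classify(X, y, k_folds=10)


class TestContingencyAndSummaries:
    def test_proportional_rows_give_zero(self):
        chi2, df, _ = stats.chi_square_independence([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 1

    def test_perfect_association_two_by_two(self):
        chi2, _, _ = stats.chi_square_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)

    def test_permutation_invariance(self, rng):
        tab = rng.integers(1, 30, (4, 3))
        a, _, _ = stats.chi_square_independence(tab)
        b, _, _ = stats.chi_square_independence(tab[::-1][:, ::-1])
        assert a == pytest.approx(b)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            stats.chi_square_independence([[0, 0], [1, 2]])

    def test_summary_anova_equals_raw_data_anova(self, rng):
        groups = [rng.normal(m, 1.0, n) for m, n in [(0, 12), (0.5, 20), (1.0, 8)]]
        F_raw, p_raw = sps.f_oneway(*groups)
        F, dfs, p = stats.anova_from_summaries(
            [len(g) for g in groups], [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups])
        assert F == pytest.approx(F_raw, rel=1e-10)
        assert p == pytest.approx(p_raw, rel=1e-10)

    def test_equal_means_zero_f(self):
        F, _, _ = stats.anova_from_summaries([10, 10], [5.0, 5.0], [1.0, 1.2])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_squared_t(self):
        F, _, _ = stats.anova_from_summaries([12, 15], [3.0, 4.1], [1.1, 0.9])
        t, _, _ = stats.two_sample_t_from_summaries(12, 3.0, 1.1, 15, 4.1, 0.9)
        assert F == pytest.approx(t ** 2, rel=1e-12)


class TestRegressorCountAnova:
    def test_identical_levels_zero_trend(self, rng):
        base = rng.normal(0, 1, (10, 1, 30))
        lbf = np.repeat(base, 4, axis=1)
        res = stats.regressor_count_anova(lbf)
        np.testing.assert_allclose(res.trend_t, 0.0, atol=1e-10)

    def test_linear_decline_detected_at_analytic_power(self, rng):
        """Noncentral-t oracle: per-subject contrast c ~ N(slope*w'levels,
        sigma^2 ||w||^2) gives a known detection rate."""
        levels = np.array([1.0, 2.0, 3.0, 5.0])
        w = levels - levels.mean()
        slope, sigma, n = -0.6, 1.0, 16
        ncp = slope * (w @ levels) / (sigma * np.linalg.norm(w) / np.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        power = sps.nct.sf(crit, n - 1, abs(ncp))
        detections = 0
        reps = 400
        for _ in range(reps):
            lbf = (slope * levels)[None, :, None] + rng.normal(0, sigma, (n, 4, 1))
            res = stats.regressor_count_anova(lbf)
            detections += res.trend_p[0] < 0.05
        assert abs(detections / reps - power) < 0.08

    def test_missing_level_rejected(self):
        lbf = np.zeros((5, 4, 2))
        lbf[0, 1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            stats.regressor_count_anova(lbf)

    def test_extract_returns_per_level_ci(self, rng):
        lbf = rng.normal(2.0, 1.0, (12, 4, 5))
        res = stats.regressor_count_anova(lbf)
        tab = res.extract(0)
        assert list(tab["n_regressors"]) == [1, 2, 3, 5]
        assert np.all(tab["ci_low"] < tab["mean_lbf"])
        assert np.all(tab["mean_lbf"] < tab["ci_high"])


class TestSecondLevel:
    def test_pure_effect_block_survives_exactly(self, rng):
        n, shape = 10, (6, 6, 2)
        V = int(np.prod(shape))
        maps = np.zeros((n, V))
        block = np.arange(12)  # a 12-voxel cluster in flat order (6x2 slab)
        maps[:, block] = 1.0 + 0.1 * np.arange(n)[:, None]
        res = stats.second_level_ftest(maps, grid_shape=shape, cluster_k=10,
                                       n_permutations=500, seed=0)
        assert set(np.flatnonzero(res.significant)) == set(block)

    def test_small_clusters_suppressed(self, rng):
        n, shape = 10, (6, 6, 2)
        maps = np.zeros((n, 72))
        maps[:, [0]] = 1.0 + 0.1 * np.arange(n)[:, None]   # single-voxel cluster
        res = stats.second_level_ftest(maps, grid_shape=shape, cluster_k=10,
                                       n_permutations=500, seed=0)
        assert res.significant.sum() == 0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            stats.second_level_ftest(np.zeros((1, 10)))

    def test_null_familywise_error_controlled(self, rng):
        """Quick calibration check (the full one runs in the acceptance suite)."""
        false_positives = 0
        reps = 100
        for _ in range(reps):
            maps = rng.normal(0, 1, (8, 50))
            res = stats.second_level_ftest(maps, n_permutations=199,
                                           cluster_k=1, seed=rng.integers(2 ** 31))
            false_positives += res.significant.any()
        assert false_positives / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_bonferroni_fallback_more_conservative(self, rng):
        maps = rng.normal(0.3, 1, (12, 40))
        perm = stats.second_level_ftest(maps, n_permutations=999, cluster_k=1, seed=1)
        bonf = stats.second_level_ftest(maps, method="bonferroni", cluster_k=1)
        assert bonf.significant.sum() <= perm.significant.sum()
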