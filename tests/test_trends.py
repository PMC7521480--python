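"""Condition summaries, robust mean-variance fits, filters, slope tests."""

import numpy as np
import pytest

import telegraphkit as tk
from telegraphkit import ConditionSummary, MeanVarianceTrend
from telegraphkit.trends import TrendTarget


def line_summaries(alpha, sigma0=0.0, means=(20, 50, 100, 200, 300, 400),
                   n_cells=500):
    return [ConditionSummary(f"c{i}", float(m), alpha * m + sigma0, n_cells)
            for i, m in enumerate(means)]


class TestSummaries:
    def test_basic_moments(self):
        out = tk.summarize_conditions({"a": [0, 2], "b": [5, 5, 5]})
        by = {s.condition: s for s in out}
        assert by["a"].mean == 1.0 and by["a"].variance == 2.0
        assert by["b"].variance == 0.0

    def test_single_cell_condition_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            out = tk.summarize_conditions({"a": [1], "b": [1, 2], "c": [3, 4]})
        assert {s.condition for s in out} == {"b", "c"}

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            tk.summarize_conditions({"only": [1, 2, 3]})

    def test_long_dataframe_input(self):
        import pandas as pd
        df = pd.DataFrame({"condition": ["x"] * 3 + ["y"] * 3,
                           "count": [1, 2, 3, 10, 20, 30]})
        out = tk.summarize_conditions(df)
        assert {s.condition for s in out} == {"x", "y"}


class TestMeanVarianceFit:
    def test_noiseless_line_recovered_to_machine_precision(self):
        trend = tk.fit_mean_variance(line_summaries(100.0))
        assert trend.alpha == pytest.approx(100.0, abs=1e-9)
        assert trend.sigma0 == pytest.approx(0.0, abs=1e-6)
        assert trend.r2 == pytest.approx(1.0, abs=1e-12)

    def test_gross_outlier_removed_by_robust_fit(self):
        summaries = line_summaries(40.0, sigma0=500.0)
        summaries.append(ConditionSummary("bad", 150.0, 40.0 * 150 * 8, 500))
        robust = tk.fit_mean_variance(summaries, robust=True)
        assert robust.alpha == pytest.approx(40.0, rel=0.05)
        assert len(robust.outlier_indices) == 1
        plain = tk.fit_mean_variance(summaries, robust=False)
        assert abs(plain.alpha - 40.0) > abs(robust.alpha - 40.0)

    def test_robust_fit_invariant_to_point_order(self):
        rng = np.random.default_rng(0)
        x = np.linspace(10, 300, 12)
        y = 30 * x + rng.normal(0, 300, size=12)
        y[3] += 2e4
        y[8] -= 1.5e4
        base = MeanVarianceTrend().fit(x, y)
        perm = rng.permutation(12)
        shuffled = MeanVarianceTrend().fit(x[perm], y[perm])
        assert shuffled.alpha_ == pytest.approx(base.alpha_, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            MeanVarianceTrend().fit([1.0, 2.0], [1.0, 2.0])

    def test_sklearn_interface(self):
        est = MeanVarianceTrend(robust=False)
        params = est.get_params()
        assert "robust" in params
        x = np.array([10.0, 20.0, 30.0, 40.0])
        est.fit(x, 5 * x + 3)
        np.testing.assert_allclose(est.predict(x), 5 * x + 3)


class TestMahalanobisFilter:
    def test_far_point_removed(self):
        x = np.linspace(10, 100, 12)
        pts = np.column_stack([x, 20 * x])
        pts = np.vstack([pts, [50.0, 20000.0]])
        kept, outliers = tk.mahalanobis_filter(pts)
        assert list(outliers) == [12]
        assert kept.shape == (12, 2)

    def test_identity_when_no_outliers(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, size=(40, 2))
        cut = 0.001  # very permissive threshold
        kept, outliers = tk.mahalanobis_filter(pts, threshold=cut)
        assert outliers.size == 0 and kept.shape == pts.shape

    def test_matches_brute_force_distances(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 1, (60, 2)) @ np.array([[2.0, 0.3], [0.3, 0.5]])
        _, outliers = tk.mahalanobis_filter(pts, threshold=0.05)
        center = pts.mean(0)
        inv = np.linalg.inv(np.cov(pts.T))
        d2 = np.array([(p - center) @ inv @ (p - center) for p in pts])
        expected = np.nonzero(d2 > stats.chi2.ppf(0.95, 2))[0]
        np.testing.assert_array_equal(outliers, expected)

    def test_singular_covariance_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(ValueError):
            tk.mahalanobis_filter(pts)


class TestGeneFilters:
    def test_boundary_and_degenerate_cases(self):
        import pandas as pd
        table = pd.DataFrame(
            {"unstim": [10.0, 30.0, 0.0, 80.0],
             "stim_1": [99.0, 150.0, 0.0, 120.0]},
            index=["below_abundance", "keeper", "all_zero", "uninduced"])
        kept = tk.gene_filters(table, baseline="unstim")
        assert list(kept) == ["keeper"]

    def test_matches_generator_truth_exactly(self):
        ds = tk.generate_nb_matrix(n_genes=40, seed=5)
        kept = tk.gene_filters(ds.true_mean_table(), baseline="unstim")
        expected = [g for g, ok in zip(ds.genes, ds.truth["passes_filters"])
                    if ok]
        assert sorted(kept) == sorted(expected)


class TestBurstinessTrends:
    def test_exact_line_gives_constant_burst_and_linear_frequency(self):
        alpha = 41.0
        fits = tk.burstiness_trends(line_summaries(alpha))
        bs = fits[TrendTarget.REL_BURST_SIZE]
        assert bs.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        fr = fits[TrendTarget.REL_FREQUENCY]
        assert fr.coefficients[0] == pytest.approx(1.0 / (alpha - 1), rel=1e-9)
        var = fits[TrendTarget.VARIANCE]
        assert var.coefficients[0] == pytest.approx(alpha, rel=1e-9)
        assert var.high_confidence and fr.high_confidence

    def test_poisson_conditions_skipped_for_frequency(self):
        summaries = line_summaries(30.0)
        summaries += [ConditionSummary("poisson", 50.0, 50.0, 500)]
        with pytest.warns(UserWarning, match="skipped"):
            fits = tk.burstiness_trends(summaries)
        assert TrendTarget.REL_FREQUENCY in fits

    def test_classification_matches_recomputed_r2(self):
        rng = np.random.default_rng(3)
        means = np.linspace(30, 300, 10)
        var = 25 * means * np.exp(rng.normal(0, 0.45, 10))  # noisy trend
        summaries = [ConditionSummary(f"c{i}", m, v, 500)
                     for i, (m, v) in enumerate(zip(means, var))]
        fits = tk.burstiness_trends(summaries, robust=False)
        for fit in fits.values():
            from telegraphkit.trends import R2_THRESHOLDS
            assert fit.high_confidence == (fit.r2 > R2_THRESHOLDS[fit.target])


class TestCompareSlopes:
    def test_identical_trends_not_significant(self):
        x = np.linspace(20, 300, 8)
        y = 60 * x + 100
        p = tk.compare_slopes((x, y + 1e-6 * x ** 2), (x, y + 1e-6 * x ** 2))
        assert p > 0.99

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        x = np.linspace(20, 300, 9)
        a = (x, 113 * x + rng.normal(0, 1500, 9))
        b = (x, 30 * x + rng.normal(0, 1500, 9))
        assert tk.compare_slopes(a, b) == pytest.approx(
            tk.compare_slopes(b, a), rel=1e-12)

    def test_power_to_separate_distinct_slopes(self):
        rng = np.random.default_rng(17)
        x = np.linspace(50, 400, 10)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            a = (x, 113 * x + rng.normal(0, 2000, x.size))
            b = (x, 30 * x + rng.normal(0, 2000, x.size))
            hits += tk.compare_slopes(a, b) < 0.01
        assert hits >= int(0.94 * n_rep)

    def test_fitted_trend_objects_accepted(self):
        x = np.linspace(10, 200, 8)
        ta = MeanVarianceTrend().fit(x, 20 * x + 5)
        tb = MeanVarianceTrend().fit(x, 90 * x - 40)
        assert tk.compare_slopes(ta, tb) < 1e-6


class TestSizeNormalize:
    def test_equal_areas_are_identity(self):
        counts = np.array([3, 9, 27.0])
        np.testing.assert_allclose(
            tk.size_normalize(counts, np.ones(3) * 2.5), counts)

    def test_double_area_halves_count(self):
        out = tk.size_normalize([10.0, 10.0], [2.0, 1.0])
        # mean area 1.5: count scaled by 1.5/area
        np.testing.assert_allclose(out, [7.5, 15.0])

    def test_normalization_removes_size_correlation(self):
        rng = np.random.default_rng(23)
        base = rng.negative_binomial(5, 5 / 105.0, size=4000)
        scaled, areas = tk.add_cell_size_noise(base, cv_area=0.3, seed=1)
        r_before = np.corrcoef(scaled, areas)[0, 1]
        r_after = np.corrcoef(tk.size_normalize(scaled, areas), areas)[0, 1]
        assert r_before > 0.15
        assert abs(r_after) < 0.05

    def test_bad_areas_rejected(self):
        with pytest.raises(ValueError):
            tk.size_normalize([1, 2], [1.0, 0.0])
        with pytest.raises(ValueError):
            tk.size_normalize([1, 2], [1.0])
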