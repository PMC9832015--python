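import itertools

import numpy as np
import pandas as pd
import pytest

import seedmorph as sm
from seedmorph import stats
from seedmorph.morphometrics import CLUSTER_FEATURES
from seedmorph.stats import MEDIAN_COLUMNS
from seedmorph.synth import DefectSpec


def make_table(values_by_line, feature="height_mm"):
    """Minimal trait table with one varying feature, others fixed."""
    rows = []
    for acc, values in values_by_line.items():
        for i, v in enumerate(values):
            row = {
                "accession_id": acc,
                "seed_id": i + 1,
                "area_mm2": 20.0,
                "width_mm": 4.0,
                "height_mm": 5.67,
                "perimeter_mm": 18.0,
                "major_axis_mm": 6.5,
                "circularity": 0.75,
                "roundness": 0.6,
            }
            row[feature] = v
            rows.append(row)
    return pd.DataFrame(rows)


class TestQCFilter:
    def test_gross_height_outlier_removed(self):
        heights = [5.67 + 0.1 * i for i in range(-5, 5)] + [99.163]
        table = make_table({"A": heights})
        kept, report = stats.qc_filter(table, outlier_ratio=10)
        assert report.n_removed_outlier == 1
        assert report.removed.height_mm.iloc[0] == 99.163
        assert kept.height_mm.max() < 10

    def test_planted_zero_rows_recovered(self):
        table, _ = sm.generate_trait_table(
            30, 50, defect_spec=DefectSpec(n_zero=7), rng_seed=4
        )
        kept, report = stats.qc_filter(table)
        assert report.n_removed_zero == 7
        assert (report.removed.qc_reason == "zero_value").sum() == 7
        assert not (kept[CLUSTER_FEATURES] == 0).any().any()

    def test_clean_table_untouched(self, table507):
        table, _ = table507
        kept, report = stats.qc_filter(table)
        assert report.n_removed_zero == report.n_removed_outlier == 0
        assert len(kept) == len(table)

    def test_counts_are_conserved(self):
        table, _ = sm.generate_trait_table(
            10, 30, defect_spec=DefectSpec(n_zero=2, n_outlier=1), rng_seed=0
        )
        kept, report = stats.qc_filter(table)
        assert len(kept) + len(report.removed) == report.n_input == len(table)

    def test_empty_table(self):
        kept, report = stats.qc_filter(pd.DataFrame(columns=CLUSTER_FEATURES))
        assert kept.empty and report.n_input == 0

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            stats.qc_filter(make_table({"A": [5.0]}), outlier_ratio=-1)


class TestNormalityScreen:
    def test_null_failure_fraction(self):
        # all lines truly near-normal: family-wise failure rate over 5
        # dependent features at alpha = 0.05 sits well below 0.40
        table, _ = sm.generate_trait_table(200, 95, rng_seed=5)
        report = stats.normality_screen(table)
        frac = report.n_failed / len(report.p_values)
        assert 0.08 <= frac <= 0.40

    def test_exponential_line_fails(self):
        rng = np.random.default_rng(0)
        table = make_table({"A": rng.exponential(1.0, 95)})
        report = stats.normality_screen(table)
        assert bool(report.fail.loc["A"])
        assert report.p_values.loc["A", "height_mm"] < 1e-6

    def test_constant_feature_untestable_not_crash(self):
        table = make_table({"A": [5.0] * 10})
        report = stats.normality_screen(table)
        assert np.isnan(report.p_values.loc["A"]).all()
        assert report.untestable == ["A"]
        assert report.n_failed == 0

    def test_tiny_line_excluded(self):
        rng = np.random.default_rng(1)
        table = make_table({"A": [1.0, 2.0], "B": rng.normal(5, 1, 50)})
        report = stats.normality_screen(table)
        assert "A" in report.untestable
        assert "A" not in report.fail.index and "B" in report.fail.index

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            stats.normality_screen(make_table({"A": [1.0, 2.0, 3.0]}), alpha=1.5)


class TestLineMedians:
    def test_median_is_robust(self):
        table = make_table({"A": [1.0, 2.0, 100.0]})
        summ = stats.line_medians(table)
        assert summ.median_height.iloc[0] == 2.0

    def test_single_record_line(self):
        table = make_table({"A": [7.5]})
        summ = stats.line_medians(table)
        assert summ.median_height.iloc[0] == 7.5
        assert summ.n_seeds.iloc[0] == 1

    def test_planted_center_recovery(self):
        # medians of 95-seed lines with 5% within-line noise recover the
        # planted centers within 2% (no line-level jitter)
        table, labels = sm.generate_trait_table(
            50, 95, rng_seed=9, line_cv=0.0
        )
        summ = stats.line_medians(table)
        centers = sm.DEFAULT_CLUSTER_CENTERS[labels[summ.accession_id].to_numpy()]
        rel_err = np.abs(summ[MEDIAN_COLUMNS].to_numpy() / centers - 1)
        assert rel_err.max() < 0.02


def brute_force_two_means(X):
    best = np.inf
    n = len(X)
    for bits in range(1, 2**n - 1):
        idx = np.array([(bits >> i) & 1 for i in range(n)], bool)
        cost = 0.0
        for side in (idx, ~idx):
            pts = X[side]
            cost += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, cost)
    return best


class TestKMeans:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 5))
        model = stats.kmeans_fit(X, 1, rng_seed=0)
        assert np.allclose(model.centroids[0], X.mean(axis=0))
        assert model.distortion == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_k_equals_n(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        model = stats.kmeans_fit(X, 8, n_restarts=20, rng_seed=0)
        assert model.distortion == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_two_partitions(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        model = stats.kmeans_fit(X, 2, n_restarts=10, rng_seed=0)
        assert model.distortion == pytest.approx(brute_force_two_means(X), rel=1e-9)

    def test_labels_one_based_and_distortion_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        model = stats.kmeans_fit(X, 4, rng_seed=0)
        assert set(model.labels) <= set(range(1, 5))
        d = ((X - model.centroids[model.labels - 1]) ** 2).sum()
        assert model.distortion == pytest.approx(d)

    def test_lloyd_iterations_never_increase_distortion(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 5))
        model = stats.kmeans_fit(X, 5, rng_seed=0)
        hist = np.array(model.distortion_history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_invalid_k(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            stats.kmeans_fit(X, 4)
        with pytest.raises(ValueError):
            stats.kmeans_fit(X, 0)

    def test_agrees_with_sklearn_on_separated_data(self, table507):
        sklearn = pytest.importorskip("sklearn.cluster")
        from sklearn.metrics import adjusted_rand_score

        table, _ = table507
        summ = stats.line_medians(table)
        X = stats.median_matrix(summ)
        ours = stats.kmeans_fit(X, 6, n_restarts=10, rng_seed=0)
        ref = sklearn.KMeans(n_clusters=6, n_init=10, random_state=0).fit(X)
        assert ours.distortion == pytest.approx(ref.inertia_, rel=1e-6)
        assert adjusted_rand_score(ours.labels, ref.labels_) == 1.0


class TestDistortionCurve:
    def test_curve_shape_and_monotonicity(self, table507):
        table, _ = table507
        X = stats.median_matrix(stats.line_medians(table))
        curve = stats.distortion_curve(X, k_max=10, n_restarts=10, rng_seed=1)
        assert curve.ks == list(range(1, 11))
        d = np.array(curve.distortions)
        assert (np.diff(d) <= 1e-9 * d[:-1]).all()
        # planted structure: large drops up to k = 6, shallow after
        assert d[4] - d[5] > 10 * (d[5] - d[6])

    def test_duplicate_dataset_scales_distortion(self):
        # distortion additivity requires both runs to find the optimum at
        # every k, so use scale-separated pairs with unambiguous partitions
        pos = np.array([10.0**i + d for i in range(6) for d in (0.0, 1.0)])
        X = np.column_stack([pos, np.zeros_like(pos)])
        X2 = np.vstack([X, X])
        c1 = stats.distortion_curve(X, k_max=6, n_restarts=10, rng_seed=0)
        c2 = stats.distortion_curve(X2, k_max=6, n_restarts=10, rng_seed=0)
        assert np.allclose(c2.distortions, 2 * np.array(c1.distortions), rtol=1e-9)

    def test_k_max_exceeding_n(self):
        with pytest.raises(ValueError):
            stats.distortion_curve(np.zeros((4, 5)), k_max=5)


class TestElbowSelection:
    def test_dominant_kink(self):
        curve = stats.DistortionCurve(ks=[1, 2, 3, 4], distortions=[100, 10, 9, 8])
        assert stats.select_k_elbow(curve) == 2

    def test_linear_curve_ties_to_smallest_k(self):
        curve = stats.DistortionCurve(ks=[1, 2, 3, 4, 5], distortions=[50, 40, 30, 20, 10])
        assert stats.select_k_elbow(curve) == 2

    def test_too_short(self):
        with pytest.raises(ValueError):
            stats.select_k_elbow(stats.DistortionCurve(ks=[1, 2], distortions=[2, 1]))

    def test_recovers_six_planted_clusters(self, table507):
        table, labels = table507
        kept, _ = stats.qc_filter(table)
        summ = stats.line_medians(kept)
        X = stats.median_matrix(summ)
        curve = stats.distortion_curve(X, k_max=10, n_restarts=10, rng_seed=1)
        k = stats.select_k_elbow(curve)
        assert k == 6
        from sklearn.metrics import adjusted_rand_score

        model = curve.model_for(6)
        planted = labels[summ.accession_id].to_numpy()
        assert adjusted_rand_score(model.labels, planted) >= 0.95


class TestKDE:
    def test_two_point_closed_form(self):
        from scipy.stats import norm

        r = stats.kde_density([-1.0, 1.0], bandwidth_rule="fixed", bandwidth=1.0,
                              grid_points=801)
        expected = 0.5 * (norm.pdf(r.grid, -1, 1) + norm.pdf(r.grid, 1, 1))
        assert np.allclose(r.density, expected, atol=1e-12)

    def test_consistency_standard_normal(self):
        from scipy.stats import norm

        rng = np.random.default_rng(6)
        x = rng.standard_normal(10000)
        r = stats.kde_density(x)
        assert np.max(np.abs(r.density - norm.pdf(r.grid))) <= 0.02

    def test_scaling_change_of_variables(self):
        rng = np.random.default_rng(7)
        x = rng.normal(5, 2, 500)
        c = 3.0
        r1 = stats.kde_density(x, bandwidth_rule="fixed", bandwidth=0.5)
        r2 = stats.kde_density(c * x, bandwidth_rule="fixed", bandwidth=0.5 * c)
        assert np.allclose(r2.density, r1.density / c, atol=1e-12)
        assert np.allclose(r2.grid, c * r1.grid)

    def test_integrates_to_one(self, table507):
        table, _ = table507
        for feat in CLUSTER_FEATURES:
            r = stats.kde_density(table[feat].to_numpy())
            integral = np.trapezoid(r.density, r.grid)
            assert 0.99 <= integral <= 1.01

    def test_density_can_exceed_one(self):
        r = stats.kde_density([0.0, 0.001, 0.002, 0.1], bandwidth_rule="fixed",
                              bandwidth=0.01)
        assert r.density.max() > 1.0
        assert (r.density >= 0).all()

    def test_degenerate_values(self):
        with pytest.raises(ValueError):
            stats.kde_density([2.0, 2.0, 2.0])


def summaries_from_matrix(X):
    df = pd.DataFrame(X, columns=MEDIAN_COLUMNS)
    df.insert(0, "accession_id", [f"L{i}" for i in range(len(X))])
    df["n_seeds"] = 10
    return df


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        X = np.column_stack([base, np.exp(base), base, base, base])
        corr = stats.spearman_matrix(summaries_from_matrix(X))
        assert corr.rho.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_feature(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        X = np.column_stack([base, -base, base, base, base])
        corr = stats.spearman_matrix(summaries_from_matrix(X))
        assert corr.rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(507, 5))
        corr = stats.spearman_matrix(summaries_from_matrix(X))
        off = corr.rho.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.12
        assert (corr.p_values.to_numpy()[~np.eye(5, dtype=bool)] > 1e-4).all()

    def test_symmetry_unit_diagonal_and_monotone_invariance(self, table507):
        table, _ = table507
        summ = stats.line_medians(table)
        corr = stats.spearman_matrix(summ)
        rho = corr.rho.to_numpy()
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)
        assert (np.abs(rho) <= 1).all()
        transformed = summ.copy()
        transformed["median_area"] = np.log(transformed["median_area"])
        corr2 = stats.spearman_matrix(transformed)
        assert np.allclose(corr2.rho.to_numpy(), rho)

    def test_constant_feature_reported_missing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        X[:, 2] = 1.0
        corr = stats.spearman_matrix(summaries_from_matrix(X))
        assert np.isnan(corr.rho.iloc[0, 2])

    def test_too_few_summaries(self):
        with pytest.raises(ValueError):
            stats.spearman_matrix(summaries_from_matrix(np.zeros((2, 5))))
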