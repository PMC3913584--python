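import numpy as np
import pytest

from scdhrv.datasets import reference_average_counts, reference_confusion_runs
from scdhrv.evaluate import (
    ConfusionCounts,
    loo_evaluate,
    metrics,
    repeat_evaluation,
    risk_trajectory,
)
from scdhrv.io import FeatureRow, FeatureTable
from scdhrv.model import KnnClassifier, KnnSpec, MlpSpec
from scdhrv.risk import ScdRiskModel


def _table(X, y, names=None):
    names = tuple(names or [f"f{j}" for j in range(X.shape[1])])
    rows = [
        FeatureRow(f"s{i}", "0", 0, {n: float(v) for n, v in zip(names, X[i])},
                   "scd" if y[i] else "normal")
        for i in range(X.shape[0])
    ]
    return FeatureTable(rows=rows, feature_names=names)


def _separable_table(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 0.3, (n, 2))
    X[:, 0] += 5.0 * y
    return _table(X, y)


def _eq_metrics(tp, tn, fp, fn):
    """Independent from-scratch recomputation of the four ratios."""
    return (
        100 * (tp + tn) / (tp + tn + fp + fn),
        100 * tp / (tp + fn),
        100 * tn / (tn + fp),
        100 * tp / (tp + fp),
    )


class TestMetrics:
    def test_perfect_counts(self):
        rep = metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.precision) == (
            100.0,
            100.0,
            100.0,
            100.0,
        )

    def test_matches_independent_recomputation_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 40, 4)
            rep = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            ac, sn, sp, p = _eq_metrics(tp, tn, fp, fn)
            assert abs(rep.accuracy - ac) < 1e-12
            assert abs(rep.sensitivity - sn) < 1e-12
            assert abs(rep.specificity - sp) < 1e-12
            assert abs(rep.precision - p) < 1e-12

    def test_zero_denominator_sentinel(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            rep = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert np.isnan(rep.sensitivity)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


class TestLooEvaluate:
    def test_perfectly_separable_table(self):
        counts = loo_evaluate(_separable_table(), KnnSpec(k=1))
        assert counts.tp + counts.tn == 20
        assert counts.fp == 0 and counts.fn == 0

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (16, 3))
        y = np.repeat([0, 1], 8)
        counts = loo_evaluate(_table(X, y), KnnSpec(k=3))
        assert counts.total == 16

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.3, (40, 2))
        y = np.repeat([0, 1], 20)
        X[:, 0] += 5.0 * y
        accs = []
        for _ in range(10):
            yp = rng.permutation(y)
            c = loo_evaluate(_table(X, yp), KnnSpec(k=7))
            accs.append((c.tp + c.tn) / c.total)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_too_small_table_rejected(self):
        t = _separable_table(n=20)
        t3 = FeatureTable(rows=t.rows[:3], feature_names=t.feature_names)
        with pytest.raises(ValueError):
            loo_evaluate(t3, KnnSpec(k=1))

    def test_nearest_neighbour_same_label_gives_perfect_loo(self):
        # constructed so every point's nearest neighbour shares its label
        X = np.array(
            [[0.0], [0.1], [5.0], [5.1], [10.0], [10.1], [15.0], [15.1]]
        )
        y = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        counts = loo_evaluate(_table(X, y), KnnSpec(k=1))
        assert counts.fp == 0 and counts.fn == 0


class TestRepeatEvaluation:
    def test_deterministic_classifier_identical_repetitions(self):
        run = repeat_evaluation(_separable_table(), KnnSpec(k=3), n_repeats=16)
        first = run.per_repetition[0]
        assert all(c == first for c in run.per_repetition)
        assert len(run.per_repetition) == 16

    def test_averaged_counts_are_cell_means(self):
        run = repeat_evaluation(_separable_table(), KnnSpec(k=3), n_repeats=4)
        assert run.averaged.tp == pytest.approx(
            np.mean([c.tp for c in run.per_repetition])
        )
        assert run.averaged.total == pytest.approx(20)

    def test_reference_run_averages(self):
        # published worked example: 16-run averages per interval
        avg1 = reference_average_counts(1)
        assert avg1.tp == pytest.approx(34.875)
        assert avg1.tn == pytest.approx(34.9375)
        avg2 = reference_average_counts(2)
        assert avg2.tn == pytest.approx(33.6875)  # printed truncated as 33.687
        for interval in (1, 2, 3, 4):
            runs = reference_confusion_runs(interval)
            assert len(runs) == 16
            assert all(c.total == 70 for c in runs)


class TestRiskTrajectory:
    def test_identical_windows_constant_trajectory(self):
        table = _separable_table()
        X, y = table.to_arrays()
        clf = KnnClassifier(KnnSpec(k=3)).fit(X, y)
        traj = risk_trajectory(np.tile(X[0], (4, 1)), clf)
        assert traj.size == 4
        assert np.allclose(traj, traj[0])

    def test_untrained_model_rejected(self):
        clf = KnnClassifier(KnnSpec(k=3))
        with pytest.raises(ValueError):
            risk_trajectory(np.zeros((2, 2)), clf)

    def test_interpolated_subject_mostly_non_decreasing(self):
        # subjects drifting from the normal to the scd centroid should show
        # rising risk across the four pre-event windows for most seeds
        wins = 0
        for seed in range(10):
            table = _separable_table(seed=seed)
            X, y = table.to_arrays()
            clf = KnnClassifier(KnnSpec(k=3)).fit(X, y)
            lo, hi = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
            path = np.array([lo + f * (hi - lo) for f in (0.1, 0.4, 0.7, 1.0)])
            traj = risk_trajectory(path, clf)
            wins += int(np.all(np.diff(traj) >= 0))
        assert wins >= 8

    def test_single_window(self):
        table = _separable_table()
        X, y = table.to_arrays()
        clf = KnnClassifier(KnnSpec(k=3)).fit(X, y)
        assert risk_trajectory(X[:1], clf).shape == (1,)


class TestRiskModelApi:
    def test_fit_returns_results_with_summary(self):
        table = _separable_table()
        res = ScdRiskModel(table, classifier=KnnSpec(k=3)).fit(n_repeats=2, seed=0)
        text = res.summary()
        assert "Accuracy" in text and "leave-one-out" in text
        assert res.accuracy == pytest.approx(100.0)
        frame = res.counts_frame()
        assert list(frame.index) == ["TP", "TN", "FP", "FN"]
        assert frame.shape == (4, 3)  # 2 repetitions + Average

    def test_from_dataframe_round_trip(self, cohort_table):
        df = cohort_table.to_dataframe()
        model = ScdRiskModel.from_dataframe(df, classifier=KnnSpec(k=7))
        X1, y1 = model.table.to_arrays()
        X0, y0 = cohort_table.to_arrays()
        assert np.allclose(X1, X0) and np.array_equal(y1, y0)
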