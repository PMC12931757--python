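"""Train/test split, grid tuning, feature selection and evaluation."""

import numpy as np
import pandas as pd
import pytest

from mafldpred.data_model import CohortTable, VariableSchema
from mafldpred.modeling import (
    GAConfig,
    aggregate_importance,
    evaluate,
    select_features,
    split_train_test,
    tune_classifier,
)
from mafldpred.synthetic import CohortSimConfig, generate_cohort

from conftest import make_small_cohort


class TestSplit:
    def test_sizes_and_stratification(self, small_schema):
        table = make_small_cohort(small_schema, n=1000, seed=1)
        # force exact balance
        table.values["y"] = np.tile([0.0, 1.0], 500)
        train, test = split_train_test(table, 0.8, seed=0)
        assert train.n_records == 800 and test.n_records == 200
        assert abs(train.values["y"].sum() - 400) <= 1

    def test_partition(self, small_cohort):
        train, test = split_train_test(small_cohort, seed=0)
        assert set(train.record_ids) | set(test.record_ids) == set(
            small_cohort.record_ids
        )
        assert not set(train.record_ids) & set(test.record_ids)

    def test_determinism(self, small_cohort):
        t1, _ = split_train_test(small_cohort, seed=5)
        t2, _ = split_train_test(small_cohort, seed=5)
        assert list(t1.record_ids) == list(t2.record_ids)


class TestTune:
    def test_singleton_grid_returned(self, small_cohort):
        best, trace = tune_classifier(
            small_cohort, "decision_tree", grid=[{"max_depth": 4}], folds=3
        )
        assert best == {"max_depth": 4}
        assert len(trace) == 3  # |grid| x folds

    def test_trace_length(self, small_cohort):
        grid = [{"max_depth": d} for d in (2, 4, 6)]
        _, trace = tune_classifier(small_cohort, "decision_tree", grid, folds=5)
        assert len(trace) == 15

    def test_ideal_depth_wins_on_interaction_data(self, small_schema):
        """A depth-1 stump cannot represent an XOR-style interaction; the
        deeper configuration in the grid wins."""
        rng = np.random.default_rng(7)
        n = 600
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = ((x1 > 0) ^ (x2 > 0)).astype(float)
        frame = pd.DataFrame(
            {"x1": x1, "x2": x2, "x3": rng.standard_normal(n),
             "b1": np.zeros(n), "y": y}
        )
        table = CohortTable(list(small_schema), frame)
        best, _ = tune_classifier(
            table, "decision_tree",
            grid=[{"max_depth": 1}, {"max_depth": 4}], folds=5,
        )
        assert best == {"max_depth": 4}


class TestSelectFeatures:
    def test_k_best_all_features_is_identity(self, small_cohort):
        sel = select_features(
            small_cohort, "select_k_best", k_grid=[4], folds=2
        )
        assert sorted(sel.selected) == ["b1", "x1", "x2", "x3"]

    def test_k_above_feature_count_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            select_features(small_cohort, "select_k_best", k_grid=[10], folds=2)

    def test_informative_feature_ranked_first(self, small_schema):
        table = make_small_cohort(small_schema, n=500, seed=2, effect=2.0)
        sel = select_features(table, "select_k_best", k_grid=[1], folds=2)
        assert sel.selected == ["x1"]

    def test_pca_component_count_bounded(self, small_cohort):
        sel = select_features(small_cohort, "pca", k_grid=[2, 4], folds=2)
        assert sel.method == "pca"
        assert sel.n_selected in (2, 4)
        Z = sel.transform(small_cohort.values[["x1", "x2", "x3", "b1"]])
        assert Z.shape == (small_cohort.n_records, sel.n_selected)

    def test_rfecv_keeps_informative_feature(self, small_schema):
        table = make_small_cohort(small_schema, n=500, seed=3, effect=2.0)
        sel = select_features(table, "rfecv", "logistic_regression", folds=3)
        assert "x1" in sel.selected

    def test_taguchi_design_runs_nine_gas(self, small_schema):
        table = make_small_cohort(small_schema, n=120, seed=4, effect=1.5)
        cfg = GAConfig(
            population_size=6, n_generations=3, folds=2, seed=0, early_stop=3
        )
        sel = select_features(
            table, "genetic_algorithm", "logistic_regression",
            ga_config=cfg, use_taguchi=True,
        )
        assert len(sel.trace) == 9
        assert sel.n_selected >= 1

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown"):
            select_features(small_cohort, "lasso_path")


class TestEvaluate:
    def _separable(self, small_schema, n=200):
        rng = np.random.default_rng(5)
        y = np.tile([0.0, 1.0], n // 2)
        frame = pd.DataFrame(
            {"x1": y * 10 + rng.random(n), "x2": rng.standard_normal(n),
             "x3": rng.standard_normal(n), "b1": np.zeros(n), "y": y}
        )
        return CohortTable(list(small_schema), frame)

    def test_separable_data_perfect_metrics_and_zero_ci(self, small_schema):
        table = self._separable(small_schema)
        train, test = split_train_test(table, seed=0)
        sel = select_features(train, "none")
        rep = evaluate(train, test, "decision_tree", sel, folds=5, n_repeats=2)
        acc = rep.cv_summary.query("metric=='accuracy' and axis=='folds'").iloc[0]
        assert acc["mean"] == 1.0
        assert acc["ci_low"] == acc["ci_high"] == 1.0  # identical folds: zero width
        assert rep.test_metrics["accuracy"] == 1.0
        assert rep.test_metrics["auc"] == 1.0

    def test_f1_is_harmonic_mean_of_precision_recall(self, small_schema):
        table = make_small_cohort(small_schema, n=400, seed=6, effect=1.0)
        train, test = split_train_test(table, seed=0)
        rep = evaluate(
            train, test, "logistic_regression", select_features(train, "none"),
            folds=5, n_repeats=1,
        )
        for _, row in rep.fold_metrics.iterrows():
            p, r = row["precision"], row["recall"]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert row["f1"] == pytest.approx(expected, abs=1e-12)

    def test_ci_contains_mean(self, small_schema):
        table = make_small_cohort(small_schema, n=300, seed=7)
        train, test = split_train_test(table, seed=0)
        rep = evaluate(
            train, test, "extra_trees", select_features(train, "none"),
            best_params={"n_estimators": 20}, folds=5, n_repeats=2,
        )
        for _, row in rep.cv_summary.iterrows():
            assert row["ci_low"] <= row["mean"] <= row["ci_high"]

    def test_selection_ignores_test_rows(self, small_schema):
        """Replacing the held-out rows with noise leaves the training-side
        feature selection unchanged (no leakage)."""
        table = make_small_cohort(small_schema, n=400, seed=8, effect=1.5)
        train, test = split_train_test(table, seed=0)
        sel1 = select_features(train, "select_k_best", k_grid=[2], folds=3, seed=0)
        noisy_test = test.copy()
        rng = np.random.default_rng(0)
        for col in ["x1", "x2", "x3"]:
            noisy_test.values[col] = rng.standard_normal(test.n_records)
        sel2 = select_features(train, "select_k_best", k_grid=[2], folds=3, seed=0)
        assert sel1.selected == sel2.selected


class TestImportance:
    def _report_with(self, cid, importances, acc):
        cv = pd.DataFrame(
            [{"metric": "accuracy", "axis": "repeats", "mean": acc, "sd": 0.0,
              "ci_low": acc, "ci_high": acc}]
        )
        from mafldpred.modeling import ModelReport

        return ModelReport(
            classifier_id=cid, selection_method="none",
            n_selected=len(importances), best_params={},
            fold_metrics=pd.DataFrame(), cv_summary=cv, test_metrics={},
            importances=importances,
        )

    def test_identical_vectors_average_to_themselves(self):
        imp = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        reps = [self._report_with(f"m{i}", imp, 0.8) for i in range(3)]
        out = aggregate_importance(reps, k=3, top_n=3)
        np.testing.assert_allclose(out["mean_importance"], [0.5, 0.3, 0.2])

    def test_one_hot_importances_tie_broken_by_name(self):
        idx = ["a", "b", "c"]
        reps = [
            self._report_with("m1", pd.Series([1.0, 0, 0], index=idx), 0.9),
            self._report_with("m2", pd.Series([0, 1.0, 0], index=idx), 0.8),
            self._report_with("m3", pd.Series([0, 0, 1.0], index=idx), 0.7),
        ]
        out = aggregate_importance(reps, k=3, top_n=3)
        np.testing.assert_allclose(out["mean_importance"], [1 / 3] * 3)
        assert list(out["feature"]) == ["a", "b", "c"]

    def test_top_n_equal_to_feature_count_returns_full_ranking(self):
        imp = pd.Series([0.6, 0.4], index=["a", "b"])
        reps = [self._report_with("m", imp, 0.8)]
        out = aggregate_importance(reps, k=1, top_n=2)
        assert len(out) == 2

    def test_model_without_importances_excluded(self, small_schema):
        table = make_small_cohort(small_schema, n=200, seed=9, effect=1.5)
        train, test = split_train_test(table, seed=0)
        sel = select_features(train, "none")
        knn = evaluate(train, test, "k_nearest_neighbors", sel, folds=3, n_repeats=1)
        tree = evaluate(train, test, "decision_tree", sel, folds=3, n_repeats=1)
        assert knn.importances is None
        out = aggregate_importance([knn, tree], k=2, top_n=4)
        assert set(out.columns) == {"feature", "decision_tree", "mean_importance"}

    def test_importances_normalized(self, small_schema):
        table = make_small_cohort(small_schema, n=200, seed=10, effect=1.5)
        train, test = split_train_test(table, seed=0)
        rep = evaluate(
            train, test, "extra_trees", select_features(train, "none"),
            best_params={"n_estimators": 20}, folds=3, n_repeats=1,
        )
        assert rep.importances.sum() == pytest.approx(1.0)
        assert (rep.importances >= 0).all()


def test_ensembles_beat_knn_on_calibrated_cohort(calibrated_cohort):
    """Directional check mirroring the published ordering: ensemble models
    outperform k-nearest-neighbours without feature selection."""
    train, test = split_train_test(calibrated_cohort, seed=0)
    sel = select_features(train, "none")
    knn = evaluate(
        train, test, "k_nearest_neighbors", sel, folds=3, n_repeats=1, seed=0
    )
    et = evaluate(
        train, test, "extra_trees", sel, best_params={"n_estimators": 60},
        folds=3, n_repeats=1, seed=0,
    )
    acc = lambda r: r.cv_summary.query("metric=='accuracy' and axis=='folds'")[
        "mean"
    ].iloc[0]
    assert acc(et) > acc(knn)
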