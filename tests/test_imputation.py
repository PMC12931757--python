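"""Imputer behaviour, scoring closed forms, and the benchmark loop."""

import numpy as np
import pandas as pd
import pytest

from mafldpred.amputation import AmputationPlan
from mafldpred.data_model import CohortTable, VariableSchema
from mafldpred.imputation import (
    BENCHMARK_METHODS,
    impute,
    run_benchmark,
    score_imputation,
)
from mafldpred.synthetic import CohortSimConfig, MissingnessConfig, generate_cohort


def _linear_table(n=1000, seed=0, mar_rate=0.2):
    """y = 2x + N(0, 0.1) with MAR missingness in y driven by x."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 2 * x + 0.1 * rng.standard_normal(n)
    z = rng.standard_normal(n)  # padding so imputers have >2 columns
    frame = pd.DataFrame({"x": x, "yv": y, "z": z})
    schema = [
        VariableSchema("x", "continuous", "", (-1e6, 1e6)),
        VariableSchema("yv", "continuous", "", (-1e6, 1e6)),
        VariableSchema("z", "continuous", "", (-1e6, 1e6)),
    ]
    order = np.argsort(-x)  # MAR: highest-x records lose y
    k = int(round(mar_rate * n))
    missing_rows = order[:k]
    truth = pd.DataFrame(
        {
            "record_id": missing_rows,
            "variable": "yv",
            "true_value": y[missing_rows],
        }
    )
    frame.loc[missing_rows, "yv"] = np.nan
    table = CohortTable(schema, frame)
    plan = AmputationPlan(
        target_ratios={"yv": mar_rate},
        amputated={"yv": list(missing_rows)},
        ground_truth=truth,
    )
    return table, plan


class TestImpute:
    def test_no_missing_cells_is_identity_with_warning(self, small_cohort):
        with pytest.warns(UserWarning, match="identity"):
            out = impute(small_cohort, "mice_ridge")
        pd.testing.assert_frame_equal(out.values, small_cohort.values)

    def test_knn_with_all_neighbors_is_column_mean(self):
        schema = [
            VariableSchema("a", "continuous", "", (-1e6, 1e6)),
            VariableSchema("b", "continuous", "", (-1e6, 1e6)),
        ]
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 20.0, 30.0, np.nan]})
        table = CohortTable(schema, frame)
        out = impute(table, "knn_imputer", params={"n_neighbors": 3})
        assert out.values.loc[3, "b"] == pytest.approx(20.0)

    def test_mice_ridge_recovers_linear_structure(self):
        table, plan = _linear_table()
        out = impute(table, "mice_ridge", seed=0)
        card = score_imputation(out, plan, "mice_ridge")
        assert card.weighted_continuous >= 0.9

    @pytest.mark.parametrize("method", BENCHMARK_METHODS + ("mean_baseline",))
    def test_observed_cells_never_altered(self, method):
        table, _ = _linear_table(n=120, seed=3)
        observed = ~table.mask
        out = impute(table, method, seed=1)
        assert not out.mask.any().any()
        for col in table.values.columns:
            obs = observed[col]
            np.testing.assert_array_equal(
                out.values.loc[obs, col].to_numpy(),
                table.values.loc[obs, col].to_numpy(),
            )

    def test_binary_imputations_are_binary_and_ranges_respected(self):
        from mafldpred.synthetic import inject_missingness

        table, _ = generate_cohort(CohortSimConfig(n_records=300, seed=2))
        masked, _ = inject_missingness(table, MissingnessConfig(seed=2))
        out = impute(masked, "mice_ridge", seed=2)
        for v in out.schema:
            col = out.values[v.name]
            if v.kind == "binary":
                assert col.isin([0.0, 1.0]).all()
            elif v.acceptable_range is not None:
                lo, hi = v.acceptable_range
                assert col.between(lo, hi).all()


class TestScoreImputation:
    def _plan(self, weights, truths):
        truth_rows = []
        amputated = {}
        for var, vals in truths.items():
            amputated[var] = list(range(len(vals)))
            for i, t in enumerate(vals):
                truth_rows.append({"record_id": i, "variable": var, "true_value": t})
        return AmputationPlan(
            target_ratios=weights,
            amputated=amputated,
            ground_truth=pd.DataFrame(truth_rows),
        )

    def _table(self, imputed_cols):
        schema = [
            VariableSchema(c, "continuous", "", (-1e6, 1e6)) for c in imputed_cols
        ]
        return CohortTable(schema, pd.DataFrame(imputed_cols))

    def test_perfect_imputation_scores_one(self):
        plan = self._plan({"a": 0.3, "b": 0.1}, {"a": [1, 2, 3], "b": [4, 5, 6]})
        table = self._table({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        card = score_imputation(table, plan)
        assert card.weighted_continuous == pytest.approx(1.0)
        assert (card.per_variable["metric"] == 1.0).all()

    def test_truth_mean_constant_gives_r2_zero(self):
        plan = self._plan({"a": 0.3}, {"a": [1.0, 2.0, 3.0]})
        table = self._table({"a": [2.0, 2.0, 2.0]})
        card = score_imputation(table, plan)
        assert card.per_variable["metric"].iloc[0] == pytest.approx(0.0)

    def test_worked_weighted_average(self):
        """Weights (0.2, 0.4) with R^2 (0.5, 0.8) aggregate to 0.7."""
        plan = self._plan({"a": 0.2, "b": 0.4}, {"a": [0.0, 1.0, 2.0], "b": [0.0, 1.0, 2.0]})
        # choose imputations realizing R^2 exactly 0.5 and 0.8 (SST = 2)
        table = self._table(
            {"a": [0.0, 0.0, 2.0], "b": [0.0, 1.0 - np.sqrt(0.4), 2.0]}
        )
        card = score_imputation(table, plan)
        np.testing.assert_allclose(
            sorted(card.per_variable["metric"]), [0.5, 0.8], atol=1e-12
        )
        assert card.weighted_continuous == pytest.approx(0.7)

    def test_equal_weights_reduce_to_plain_mean(self):
        plan = self._plan(
            {"a": 0.25, "b": 0.25}, {"a": [0.0, 1.0, 2.0], "b": [0.0, 1.0, 2.0]}
        )
        table = self._table({"a": [0.0, 0.0, 2.0], "b": [0.0, 1.0 - np.sqrt(0.4), 2.0]})
        card = score_imputation(table, plan)
        assert card.weighted_continuous == pytest.approx((0.5 + 0.8) / 2)

    def test_invariant_to_variable_order(self):
        plan = self._plan({"a": 0.2, "b": 0.4}, {"a": [0.0, 1.0, 2.0], "b": [3.0, 4.0, 5.0]})
        t1 = self._table({"a": [0.1, 1.0, 2.0], "b": [3.0, 4.2, 5.0]})
        schema_rev = list(reversed(t1.schema))
        t2 = CohortTable(schema_rev, t1.values[["b", "a"]])
        c1 = score_imputation(t1, plan)
        c2 = score_imputation(t2, plan)
        assert c1.weighted_continuous == pytest.approx(c2.weighted_continuous)


def _strong_structure_cohort(n=1200, seed=5):
    """Calibrated cohort with a high-correlation copula (strong linear
    structure) and moderate MAR missingness."""
    from mafldpred.data_model import default_schema
    from mafldpred.synthetic import default_correlation, inject_missingness

    schema = default_schema()
    names = [v.name for v in schema if v.role == "feature"]
    R = pd.DataFrame(0.7 * np.ones((len(names), len(names))), index=names, columns=names)
    np.fill_diagonal(R.to_numpy(), 1.0)
    table, _ = generate_cohort(
        CohortSimConfig(n_records=n, seed=seed, correlation=R)
    )
    rates = {"ALT": 0.25, "AST": 0.2, "Insulin": 0.3, "CRP": 0.2, "Waist": 0.15}
    masked, _ = inject_missingness(
        table, MissingnessConfig(rates=rates, seed=seed)
    )
    return masked


def test_benchmark_nine_scorecards_and_linear_structure():
    """One seed of the full benchmark: all nine methods produce scorecards,
    reruns are identical, and with strong linear structure the best
    chained-equations method beats the mean baseline."""
    from mafldpred.estimators import TINY_GRIDS

    table = _strong_structure_cohort()
    light = {"n_estimators": 10}
    kwargs = dict(
        seeds=(0,), folds=3, grids=TINY_GRIDS,
        classifier_ids=("logistic_regression",), min_complete=50,
        method_params={
            "mice_random_forest": light,
            "mice_extra_trees": light,
            "mice_adaboost": light,
            "mice_gbdt": light,
            "missforest": {"n_estimators": 10},
        },
    )
    bench = run_benchmark(table, **kwargs)
    methods = {sc.method_id for sc in bench.scorecards}
    assert set(BENCHMARK_METHODS) <= methods
    assert sum(sc.method_id != "mean_baseline" for sc in bench.scorecards) == 9

    again = run_benchmark(table, **kwargs)
    for a, b in zip(bench.scorecards, again.scorecards):
        assert a.method_id == b.method_id
        assert a.weighted_continuous == pytest.approx(b.weighted_continuous)

    summary = bench.summary.set_index("method")["weighted_continuous"]
    mice = summary[[m for m in summary.index if m.startswith("mice")]]
    assert mice.max() > summary["mean_baseline"]
    assert bench.winner != "mean_baseline"
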