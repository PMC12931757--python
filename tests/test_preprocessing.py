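"""Cleaning, sensitivity analysis, LOF outliers and class balancing."""

import numpy as np
import pandas as pd
import pytest

from mafldpred.data_model import CohortTable, VariableSchema
from mafldpred.preprocessing import (
    apply_range_filter,
    balance_smote,
    balance_undersample,
    detect_outliers_lof,
    drop_sparse,
    sensitivity_analysis,
    smd,
)
from mafldpred.synthetic import CohortSimConfig, MissingnessConfig, generate_cohort, inject_missingness

from conftest import make_small_cohort


class TestRangeFilter:
    def test_out_of_range_cell_nulled(self, small_schema):
        table = make_small_cohort(small_schema, n=10)
        table.values.loc[0, "x1"] = -500.0  # range is (-100, 100)
        out, rep = apply_range_filter(table)
        assert bool(out.mask.loc[0, "x1"])
        assert rep.cells_nulled_by_range == {"x1": 1}

    def test_in_range_identity(self, small_cohort):
        out, rep = apply_range_filter(small_cohort)
        pd.testing.assert_frame_equal(out.values, small_cohort.values)
        assert rep.cells_nulled_by_range == {}

    def test_boundary_value_retained(self, small_schema):
        table = make_small_cohort(small_schema, n=5)
        table.values.loc[0, "x1"] = 100.0  # closed interval endpoint
        out, _ = apply_range_filter(table)
        assert not bool(out.mask.loc[0, "x1"])


class TestDropSparse:
    def _table_with_missing(self, small_schema, col_frac):
        table = make_small_cohort(small_schema, n=100, seed=1)
        for col, frac in col_frac.items():
            table.values.loc[: int(frac * 100) - 1, col] = np.nan
        return table

    def test_feature_above_threshold_dropped(self, small_schema):
        table = self._table_with_missing(small_schema, {"x2": 0.46})
        out, rep = drop_sparse(table)
        assert "x2" not in out.values.columns
        assert list(rep.features_dropped) == ["x2"]

    def test_feature_at_threshold_retained(self, small_schema):
        table = self._table_with_missing(small_schema, {"x2": 0.45})
        out, _ = drop_sparse(table)
        assert "x2" in out.values.columns

    def test_sparse_row_dropped(self, small_schema):
        table = make_small_cohort(small_schema, n=40)
        table.values.loc[0, ["x1", "x2", "x3"]] = np.nan  # 3/4 features
        out, rep = drop_sparse(table)
        assert 0 not in out.record_ids
        assert rep.rows_dropped_missing == 1

    def test_duplicates_dropped_first_kept(self, small_schema):
        table = make_small_cohort(small_schema, n=30)
        table.values.iloc[5] = table.values.iloc[2]
        out, rep = drop_sparse(table)
        assert rep.rows_dropped_duplicate == 1
        assert table.record_ids[2] in out.record_ids

    def test_idempotent(self, small_schema):
        table = self._table_with_missing(small_schema, {"x2": 0.5, "x3": 0.2})
        once, _ = drop_sparse(table)
        twice, rep2 = drop_sparse(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        assert not rep2.features_dropped and rep2.rows_dropped_missing == 0


class TestSensitivity:
    def test_identical_scenarios_give_null_differences(self, small_cohort):
        rep = sensitivity_analysis(small_cohort, thresholds=(0.3, 0.45, 0.6))
        assert (rep.table["smd"] == 0).all()
        assert (rep.table["ks_p"] == 1.0).all()

    def test_smd_of_variable_against_itself_is_zero(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert smd(x, x) == 0.0

    def test_low_rate_cohort_scenarios_coincide(self):
        """All per-column rates < 30%: the three threshold scenarios keep
        identical cohorts, so every SMD < 0.01 and KS p = 1."""
        table, _ = generate_cohort(CohortSimConfig(n_records=600, seed=9))
        rates = {"ALT": 0.15, "CRP": 0.2, "Insulin": 0.25}
        masked, _ = inject_missingness(
            table, MissingnessConfig(rates=rates, seed=9)
        )
        rep = sensitivity_analysis(masked)
        assert not rep.table.empty
        assert (rep.table["smd"] < 0.01).all()
        assert (rep.table["ks_p"] == 1.0).all()


class TestLOF:
    def _cluster_with_outlier(self, small_schema, n=100):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(
            {
                "x1": rng.uniform(0, 1, n),
                "x2": rng.uniform(0, 1, n),
                "x3": rng.uniform(0, 1, n),
                "b1": np.zeros(n),
                "y": rng.integers(0, 2, n).astype(float),
            }
        )
        frame.loc[0, ["x1", "x2", "x3"]] = 100.0
        return CohortTable(list(small_schema), frame)

    def test_distant_point_flagged(self, small_schema):
        table = self._cluster_with_outlier(small_schema)
        flagged, scores = detect_outliers_lof(table, k_neighbors=10)
        assert 0 in flagged
        assert scores.loc[0] == scores.max()

    def test_identical_points_not_flagged(self, small_schema):
        frame = pd.DataFrame(
            {
                "x1": np.ones(50),
                "x2": np.ones(50),
                "x3": np.ones(50),
                "b1": np.zeros(50),
                "y": np.tile([0.0, 1.0], 25),
            }
        )
        table = CohortTable(list(small_schema), frame)
        flagged, _ = detect_outliers_lof(table, k_neighbors=5)
        assert len(flagged) == 0

    def test_k_too_large_rejected(self, small_schema):
        table = self._cluster_with_outlier(small_schema, n=20)
        with pytest.raises(ValueError, match="k_neighbors"):
            detect_outliers_lof(table, k_neighbors=20)

    def test_affine_rescale_invariance(self, small_schema):
        table = self._cluster_with_outlier(small_schema)
        f1, s1 = detect_outliers_lof(table, k_neighbors=10)
        rescaled = table.copy()
        rescaled.values["x2"] = 1000.0 * rescaled.values["x2"] + 5.0
        f2, s2 = detect_outliers_lof(rescaled, k_neighbors=10)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), rtol=1e-9)
        assert list(f1) == list(f2)


class TestBalancing:
    def _imbalanced(self, small_schema, n0, n1, seed=0):
        rng = np.random.default_rng(seed)
        n = n0 + n1
        frame = pd.DataFrame(
            {
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
                "x3": rng.standard_normal(n),
                "b1": rng.integers(0, 2, n).astype(float),
                "y": np.r_[np.zeros(n0), np.ones(n1)],
            },
            index=pd.RangeIndex(n, name="record_id"),
        )
        return CohortTable(list(small_schema), frame)

    def test_published_count_arithmetic(self, small_schema):
        """Pre-balancing counts 1913/1827 undersample to 3654 records."""
        table = self._imbalanced(small_schema, 1913, 1827)
        out = balance_undersample(table, seed=0)
        assert out.n_records == 3654
        counts = out.values["y"].value_counts()
        assert counts[0.0] == counts[1.0] == 1827

    def test_undersample_already_balanced_identity(self, small_schema):
        table = self._imbalanced(small_schema, 50, 50)
        out = balance_undersample(table, seed=0)
        assert out.n_records == 100

    def test_undersample_is_subset(self, small_schema):
        table = self._imbalanced(small_schema, 80, 50)
        out = balance_undersample(table, seed=1)
        assert set(out.record_ids) <= set(table.record_ids)

    def test_smote_counts(self, small_schema):
        table = self._imbalanced(small_schema, 20, 10)
        out = balance_smote(table, k_neighbors=3, seed=0)
        counts = out.values["y"].value_counts()
        assert counts[0.0] == counts[1.0] == 20
        assert set(table.record_ids) <= set(out.record_ids)  # superset

    def test_smote_points_lie_on_minority_segments(self, small_schema):
        table = self._imbalanced(small_schema, 25, 12, seed=3)
        out = balance_smote(table, k_neighbors=3, seed=3)
        new_ids = out.record_ids.difference(table.record_ids)
        minority = table.values[table.values["y"] == 1.0]
        cont = ["x1", "x2", "x3"]
        M = minority[cont].to_numpy()
        for rid in new_ids:
            s = out.values.loc[rid, cont].to_numpy()
            on_segment = False
            for i in range(len(M)):
                for j in range(len(M)):
                    if i == j:
                        continue
                    d = M[j] - M[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    lam = (s - M[i]) @ d / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                        s, M[i] + lam * d, atol=1e-9
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_smote_balanced_input_identity(self, small_schema):
        table = self._imbalanced(small_schema, 30, 30)
        out = balance_smote(table, k_neighbors=3, seed=0)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_smote_k_too_large_rejected(self, small_schema):
        table = self._imbalanced(small_schema, 20, 4)
        with pytest.raises(ValueError, match="k_neighbors"):
            balance_smote(table, k_neighbors=5, seed=0)
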