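"""Learned-MAR amputation: replicate a dataset's observed missingness
mechanism onto a fully observed subset.

The procedure splits the data into two halves.  One half supplies a fully
observed subset (rows with no missing cells) that will receive artificial
missingness.  On the other half, each column with missing values is taken in
turn as a binary target (missing = 1, observed = 0) and eight candidate
classifiers are grid-search tuned to predict missingness from the remaining
columns; the best by cross-validated F1 becomes that column's missingness
model.  Each chosen model then scores every record of the complete subset,
and the top ``round(rate * n)`` records by predicted missingness probability
are set to null — so the realized per-column rate replicates the rate
observed in the reference data exactly, while the *pattern* of which records
lose which cells follows the learned mechanism.

All columns' null sets are computed from the pre-amputation complete values
and applied jointly (simultaneous amputation); a sequential mode, in which
earlier columns' nulls are visible to later predictions, is available behind
a flag since the order of application is otherwise a hidden degree of
freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .data_model import CohortTable
from .estimators import (
    DEFAULT_GRIDS,
    MISSINGNESS_CLASSIFIERS,
    make_classifier,
)

logger = logging.getLogger(__name__)


class InvalidRatioError(ValueError):
    pass


@dataclass(frozen=True)
class MissingnessClassifierChoice:
    column: str
    classifier_id: str
    best_params: dict
    cv_f1: float


@dataclass
class AmputationPlan:
    """Per-column amputation bookkeeping.

    ``target_ratios`` are the observed missingness fractions being
    replicated; ``probabilities`` the per-record predicted missingness
    scores on the complete subset; ``amputated`` the chosen record ids; and
    ``ground_truth`` the tidy (record_id, variable, true_value) frame of
    masked cells.
    """

    target_ratios: dict[str, float] = field(default_factory=dict)
    probabilities: dict[str, pd.Series] = field(default_factory=dict)
    amputated: dict[str, list] = field(default_factory=dict)
    ground_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    choices: dict[str, MissingnessClassifierChoice] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "target_ratios": self.target_ratios,
            "amputated": {c: list(map(int, v)) for c, v in self.amputated.items()},
            "choices": {
                c: {
                    "classifier_id": ch.classifier_id,
                    "best_params": ch.best_params,
                    "cv_f1": ch.cv_f1,
                }
                for c, ch in self.choices.items()
            },
        }


# ---------------------------------------------------------------------------


def split_halves(table: CohortTable, seed: int = 0) -> tuple[CohortTable, CohortTable]:
    """Random disjoint halves (sizes differ by at most one)."""
    n = table.n_records
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = table.record_ids.to_numpy()
    half = n // 2 + (n % 2 and rng.integers(2))  # odd n: seed decides 51/50
    a, b = ids[perm[:half]], ids[perm[half:]]
    return table.subset(a), table.subset(b)


def extract_complete_subset(half: CohortTable) -> CohortTable:
    """Rows with no missing cells; empty result is allowed (with a warning)."""
    complete = ~half.mask.any(axis=1)
    out = half.subset(half.record_ids[complete])
    if out.n_records == 0:
        warnings.warn("complete subset is empty", stacklevel=2)
    return out


def _placeholder_fill(values: pd.DataFrame, table: CohortTable) -> pd.DataFrame:
    """Median (continuous) / mode (binary) fill of predictor columns, used
    only while training the missingness classifiers."""
    out = values.copy()
    for v in table.schema:
        if v.name not in out.columns:
            continue
        col = out[v.name]
        if col.isna().any():
            if v.kind == "binary":
                obs = col.dropna()
                fill = float(obs.mode().iloc[0]) if len(obs) else 0.0
            else:
                fill = float(col.median()) if col.notna().any() else 0.0
            out[v.name] = col.fillna(fill)
    return out


def _grid_search_f1(
    X: np.ndarray,
    y: np.ndarray,
    classifier_id: str,
    grid: Sequence[dict],
    folds: int,
    seed: int,
) -> tuple[dict, float]:
    """Mean CV F1 over a parameter grid; ties broken by grid order."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_params, best_f1 = None, -np.inf
    for params in grid:
        scores = []
        for tr, te in splits:
            clf = make_classifier(classifier_id, seed=seed, **params)
            clf.fit(X[tr], y[tr])
            scores.append(f1_score(y[te], clf.predict(X[te]), zero_division=0))
        mean_f1 = float(np.mean(scores))
        if mean_f1 > best_f1:
            best_params, best_f1 = params, mean_f1
    return dict(best_params), best_f1


def fit_missingness_classifiers(
    half_b: CohortTable,
    folds: int = 5,
    grids: Mapping[str, Sequence[dict]] | None = None,
    seed: int = 0,
    classifier_ids: Sequence[str] = MISSINGNESS_CLASSIFIERS,
) -> list[MissingnessClassifierChoice]:
    """One tuned missingness classifier per column with missing values.

    Columns that are entirely missing or entirely observed are skipped.
    Selection is by mean cross-validated F1; ties between classifiers are
    broken by the order of ``classifier_ids``.
    """
    if half_b.n_records == 0:
        raise ValueError("reference half is empty")
    grids = grids or DEFAULT_GRIDS
    target = half_b.target_name
    predictor_cols = [c for c in half_b.values.columns if c != target]
    filled = _placeholder_fill(half_b.values[predictor_cols], half_b)
    mask = half_b.mask

    choices = []
    for col in predictor_cols:
        y = mask[col].to_numpy().astype(int)
        n_missing = int(y.sum())
        if n_missing == 0 or n_missing == len(y):
            logger.info("column %s skipped (no class contrast)", col)
            continue
        X = filled.drop(columns=[col]).to_numpy()
        n_folds = min(folds, n_missing, len(y) - n_missing)
        if n_folds < 2:
            logger.info("column %s skipped (too few minority records)", col)
            continue
        best = None
        for cid in classifier_ids:
            params, cv_f1 = _grid_search_f1(X, y, cid, grids[cid], n_folds, seed)
            if best is None or cv_f1 > best.cv_f1:
                best = MissingnessClassifierChoice(col, cid, params, cv_f1)
        choices.append(best)
    return choices


def predict_missingness_probability(
    half_b: CohortTable,
    complete_subset: CohortTable,
    choice: MissingnessClassifierChoice,
    seed: int = 0,
) -> pd.Series:
    """Refit the chosen classifier on the reference half and score the
    complete subset's records."""
    target = half_b.target_name
    predictor_cols = [c for c in half_b.values.columns if c != target]
    filled = _placeholder_fill(half_b.values[predictor_cols], half_b)
    y = half_b.mask[choice.column].to_numpy().astype(int)
    X = filled.drop(columns=[choice.column]).to_numpy()
    clf = make_classifier(choice.classifier_id, seed=seed, **choice.best_params)
    clf.fit(X, y)
    Xc = (
        complete_subset.values[predictor_cols]
        .drop(columns=[choice.column])
        .to_numpy()
    )
    proba = clf.predict_proba(Xc)[:, 1]
    return pd.Series(proba, index=complete_subset.record_ids, name=choice.column)


def amputate(
    complete_subset: CohortTable,
    half_b: CohortTable,
    choices: Sequence[MissingnessClassifierChoice],
    target_ratios: Mapping[str, float],
    seed: int = 0,
    sequential: bool = False,
) -> tuple[AmputationPlan, CohortTable]:
    """Probability-ranked amputation of the complete subset.

    For each column with a choice and a positive target ratio, exactly
    ``round(ratio * n)`` cells are nulled — the records with the highest
    predicted missingness probability.  Predictions use the pre-amputation
    complete values unless ``sequential`` is set, in which case columns are
    processed in ``choices`` order with earlier nulls median-filled.
    """
    n = complete_subset.n_records
    if n == 0:
        raise ValueError("complete subset is empty")
    for col, ratio in target_ratios.items():
        if ratio >= 1:
            raise InvalidRatioError(f"{col}: ratio {ratio} >= 1")
        if ratio < 0:
            raise InvalidRatioError(f"{col}: negative ratio")

    plan = AmputationPlan(target_ratios=dict(target_ratios))
    work = complete_subset.copy()
    truth_rows = []
    source = complete_subset  # predictions from pre-amputation values

    for choice in choices:
        col = choice.column
        ratio = target_ratios.get(col, 0.0)
        plan.choices[col] = choice
        if ratio == 0.0:
            plan.amputated[col] = []
            continue
        basis = work if sequential else source
        basis_filled = CohortTable(
            list(basis.schema), _placeholder_fill(basis.values, basis)
        ) if sequential else basis
        proba = predict_missingness_probability(half_b, basis_filled, choice, seed=seed)
        plan.probabilities[col] = proba
        k = int(round(ratio * n))
        frame = proba.rename("p").rename_axis("rid").reset_index()
        frame = frame.sort_values(["p", "rid"], ascending=[False, True], kind="stable")
        ids = frame["rid"].iloc[:k].tolist()
        plan.amputated[col] = ids
        for rid in ids:
            truth_rows.append(
                {
                    "record_id": rid,
                    "variable": col,
                    "true_value": complete_subset.values.at[rid, col],
                }
            )
        if sequential:
            work.values.loc[ids, col] = np.nan

    if not sequential:
        for col, ids in plan.amputated.items():
            if ids:
                work.values.loc[ids, col] = np.nan
    plan.ground_truth = pd.DataFrame(
        truth_rows, columns=["record_id", "variable", "true_value"]
    )
    return plan, work
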