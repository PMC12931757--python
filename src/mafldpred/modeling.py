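"""Classifier evaluation grid: stratified 80/20 split, grid-search CV, four
feature-selection strategies, eight classifiers, CI-reported metrics and
feature-importance aggregation.

Feature selection strategies
----------------------------
* ``select_k_best`` — univariate filter: ANOVA F for continuous features,
  mutual information for binary features, merged on within-family percentile
  ranks (the raw scores of the two families are not on a common scale); the
  kept count k is tuned by cross-validated accuracy of the wrapped
  classifier.
* ``pca`` — standardized principal components, component count tuned the
  same way.
* ``rfecv`` — recursive feature elimination: features are dropped one at a
  time by model importance (coefficient magnitude or impurity importance; a
  logistic surrogate ranks for models that expose neither), and the subset
  size with the best cross-validated accuracy of the wrapped classifier is
  kept.
* ``genetic_algorithm`` — wrapper search over binary feature masks with
  cross-validated accuracy as fitness; the GA's own hyperparameters
  (population size, crossover rate, mutation rate) are chosen with a Taguchi
  L9 orthogonal array — each of the nine rows is run once and the best row's
  result is adopted.

Metrics are accuracy / precision / recall / F1 at threshold 0.5 plus
threshold-free AUC, reported per fold with mean, SD and a t-based 95% CI,
and repeated across seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .data_model import CohortTable
from .estimators import DEFAULT_GRIDS, make_classifier

logger = logging.getLogger(__name__)


def _xy(table: CohortTable) -> tuple[pd.DataFrame, np.ndarray]:
    target = table.target_name
    X = table.values[[c for c in table.values.columns if c != target]]
    y = table.values[target].to_numpy().astype(int)
    return X, y


# ---------------------------------------------------------------------------
# split and tuning


def split_train_test(
    table: CohortTable, fraction: float = 0.8, seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Stratified train/test split on the target."""
    _, y = _xy(table)
    if min(np.bincount(y)) < 2:
        raise ValueError("each class needs at least 2 records to stratify")
    train_ids, test_ids = train_test_split(
        table.record_ids.to_numpy(),
        train_size=fraction,
        stratify=y,
        random_state=seed,
    )
    return table.subset(np.sort(train_ids)), table.subset(np.sort(test_ids))


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    make_model: Callable[[], object],
    folds: int,
    seed: int,
) -> tuple[float, list[float]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(X, y):
        model = make_model()
        model.fit(X[tr], y[tr])
        scores.append(accuracy_score(y[te], model.predict(X[te])))
    return float(np.mean(scores)), scores


def tune_classifier(
    train: CohortTable,
    classifier_id: str,
    grid: Sequence[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search by stratified k-fold mean accuracy.

    Ties are broken by grid order; a configuration that raises is recorded
    as failed and excluded.  Returns (best_params, trace) where the trace
    has one row per grid cell x fold.
    """
    grid = list(grid if grid is not None else DEFAULT_GRIDS[classifier_id])
    if not grid:
        raise ValueError("empty grid")
    X_frame, y = _xy(train)
    X = X_frame.to_numpy()
    rows = []
    best_params, best_acc = None, -np.inf
    for i, params in enumerate(grid):
        try:
            mean_acc, scores = _cv_accuracy(
                X, y, lambda: make_classifier(classifier_id, seed=seed, **params),
                folds, seed,
            )
        except Exception as err:  # failed cell: logged, excluded
            logger.warning("grid cell %s failed: %s", params, err)
            for f in range(folds):
                rows.append({"cell": i, "fold": f, "accuracy": np.nan, "failed": True,
                             **{f"param_{k}": v for k, v in params.items()}})
            continue
        for f, s in enumerate(scores):
            rows.append({"cell": i, "fold": f, "accuracy": s, "failed": False,
                         **{f"param_{k}": v for k, v in params.items()}})
        if mean_acc > best_acc:
            best_params, best_acc = params, mean_acc
    if best_params is None:
        raise RuntimeError("every grid cell failed")
    return dict(best_params), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature selection


@dataclass
class SelectionResult:
    method: str
    selected: list[str] | int  # feature names, or component count for PCA
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    _scaler: StandardScaler | None = None
    _pca: PCA | None = None

    @property
    def n_selected(self) -> int:
        return self.selected if isinstance(self.selected, int) else len(self.selected)

    def transform(self, X_frame: pd.DataFrame) -> np.ndarray:
        if self.method == "pca":
            return self._pca.transform(self._scaler.transform(X_frame.to_numpy()))
        return X_frame[self.selected].to_numpy()


def _univariate_scores(
    X_frame: pd.DataFrame, y: np.ndarray, schema_kinds: Mapping[str, str], seed: int
) -> pd.Series:
    """Merged univariate relevance: percentile rank of ANOVA F within the
    continuous family and of mutual information within the binary family."""
    cont = [c for c in X_frame.columns if schema_kinds[c] == "continuous"]
    binr = [c for c in X_frame.columns if schema_kinds[c] == "binary"]
    merged = pd.Series(0.0, index=X_frame.columns)
    if cont:
        F, _ = f_classif(X_frame[cont].to_numpy(), y)
        merged[cont] = pd.Series(F, index=cont).rank(pct=True).to_numpy()
    if binr:
        mi = mutual_info_classif(
            X_frame[binr].to_numpy(), y, discrete_features=True, random_state=seed
        )
        merged[binr] = pd.Series(mi, index=binr).rank(pct=True).to_numpy()
    return merged


def _rank_features(model, feature_names: Sequence[str]) -> np.ndarray | None:
    """Per-feature importance magnitude from a fitted model, or None."""
    est = model
    if hasattr(est, "named_steps"):
        est = est.named_steps["model"]
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_, dtype=float)).ravel()
    return None


# -- genetic algorithm ------------------------------------------------------

#: L9 orthogonal array: 4 three-level factors in 9 runs (columns beyond the
#: tuned factors are ignored)
TAGUCHI_L9 = np.array(
    [
        [0, 0, 0, 0],
        [0, 1, 1, 1],
        [0, 2, 2, 2],
        [1, 0, 1, 2],
        [1, 1, 2, 0],
        [1, 2, 0, 1],
        [2, 0, 2, 1],
        [2, 1, 0, 2],
        [2, 2, 1, 0],
    ]
)


@dataclass
class GAConfig:
    population_size: int = 20
    n_generations: int = 40
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    tournament_size: int = 3
    elitism: int = 1
    early_stop: int = 10  # stagnant generations before stopping
    folds: int = 5
    seed: int = 0
    #: levels for the Taguchi array, in factor order
    taguchi_levels: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "population_size": (10, 20, 30),
            "crossover_rate": (0.6, 0.8, 0.9),
            "mutation_rate": (0.01, 0.05, 0.10),
        }
    )

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


def _ga_run(
    X: np.ndarray,
    y: np.ndarray,
    fitness: Callable[[tuple], float],
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, list[float]]:
    """One GA run over binary feature masks; returns (best mask, best
    fitness, per-generation best-fitness history)."""
    p = X.shape[1]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(p)] = True
        return mask

    pop = [repair(rng.random(p) < 0.5) for _ in range(config.population_size)]
    fits = np.array([fitness(tuple(m)) for m in pop])
    best_i = int(np.argmax(fits))
    best_mask, best_fit = pop[best_i].copy(), float(fits[best_i])
    history = [best_fit]
    stagnant = 0

    for _ in range(config.n_generations):
        new_pop = []
        elite_order = np.argsort(-fits, kind="stable")[: config.elitism]
        for i in elite_order:
            new_pop.append(pop[i].copy())
        while len(new_pop) < config.population_size:
            def tournament() -> np.ndarray:
                idx = rng.integers(0, len(pop), size=config.tournament_size)
                return pop[idx[np.argmax(fits[idx])]]
            pa, pb = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                take = rng.random(p) < 0.5  # uniform crossover
                child = np.where(take, pa, pb)
            else:
                child = pa.copy()
            flip = rng.random(p) < config.mutation_rate
            child = repair(np.logical_xor(child, flip))
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(tuple(m)) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_mask, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)
        if stagnant >= config.early_stop:
            break
    return best_mask, best_fit, history


def ga_select(
    X_frame: pd.DataFrame,
    y: np.ndarray,
    classifier_id: str,
    classifier_params: Mapping | None = None,
    config: GAConfig | None = None,
    use_taguchi: bool = True,
) -> SelectionResult:
    """Genetic-algorithm wrapper selection with CV-accuracy fitness."""
    config = config or GAConfig()
    X = X_frame.to_numpy()
    params = dict(classifier_params or {})
    cache: dict[tuple, float] = {}

    def fitness(mask_key: tuple) -> float:
        if mask_key not in cache:
            mask = np.array(mask_key, dtype=bool)
            acc, _ = _cv_accuracy(
                X[:, mask],
                y,
                lambda: make_classifier(classifier_id, seed=config.seed, **params),
                config.folds,
                config.seed,
            )
            cache[mask_key] = acc
        return cache[mask_key]

    rng = np.random.default_rng(config.seed)
    trace_rows = []
    if use_taguchi:
        factors = list(config.taguchi_levels)
        best = None
        for row_idx, row in enumerate(TAGUCHI_L9):
            cfg_kwargs = {
                f: config.taguchi_levels[f][row[i]] for i, f in enumerate(factors)
            }
            run_cfg = GAConfig(
                **{
                    **{
                        "n_generations": config.n_generations,
                        "tournament_size": config.tournament_size,
                        "elitism": config.elitism,
                        "early_stop": config.early_stop,
                        "folds": config.folds,
                        "seed": config.seed,
                    },
                    **cfg_kwargs,
                }
            )
            mask, fit, history = _ga_run(X, y, fitness, run_cfg, rng)
            trace_rows.append(
                {"run": row_idx, **cfg_kwargs, "best_fitness": fit,
                 "generations": len(history) - 1}
            )
            if best is None or fit > best[1]:
                best = (mask, fit)
        mask, fit = best
    else:
        mask, fit, history = _ga_run(X, y, fitness, config, rng)
        trace_rows.append(
            {"run": 0, "best_fitness": fit, "generations": len(history) - 1}
        )
    selected = [c for c, m in zip(X_frame.columns, mask) if m]
    return SelectionResult("genetic_algorithm", selected, pd.DataFrame(trace_rows))


def select_features(
    train: CohortTable,
    method: str,
    classifier_id: str = "logistic_regression",
    classifier_params: Mapping | None = None,
    folds: int = 5,
    seed: int = 0,
    k_grid: Sequence[int] | None = None,
    ga_config: GAConfig | None = None,
    use_taguchi: bool = True,
) -> SelectionResult:
    """Fit a feature-selection strategy on the training cohort only."""
    X_frame, y = _xy(train)
    p = X_frame.shape[1]
    params = dict(classifier_params or {})
    kinds = {v.name: v.kind for v in train.schema}

    def cv_with(cols_or_X) -> float:
        Xs = (
            X_frame[cols_or_X].to_numpy()
            if isinstance(cols_or_X, list)
            else cols_or_X
        )
        acc, _ = _cv_accuracy(
            Xs, y, lambda: make_classifier(classifier_id, seed=seed, **params),
            folds, seed,
        )
        return acc

    if method == "none":
        return SelectionResult("none", list(X_frame.columns))

    if method == "select_k_best":
        grid = list(k_grid) if k_grid else sorted({max(1, p // 4), p // 2, 3 * p // 4, p})
        if max(grid) > p:
            raise ValueError(f"k={max(grid)} exceeds feature count {p}")
        scores = _univariate_scores(X_frame, y, kinds, seed)
        order = scores.sort_values(ascending=False, kind="stable").index
        rows, best = [], None
        for k in grid:
            cols = list(order[:k])
            acc = cv_with(cols)
            rows.append({"k": k, "cv_accuracy": acc})
            if best is None or acc > best[1]:
                best = (cols, acc)
        return SelectionResult("select_k_best", best[0], pd.DataFrame(rows))

    if method == "pca":
        grid = list(k_grid) if k_grid else sorted({max(1, p // 4), p // 2, 3 * p // 4, p})
        grid = [k for k in grid if k <= p]
        scaler = StandardScaler().fit(X_frame.to_numpy())
        Z = scaler.transform(X_frame.to_numpy())
        full = PCA(n_components=p, random_state=seed).fit(Z)
        rows, best = [], None
        for k in grid:
            acc = cv_with(full.transform(Z)[:, :k])
            rows.append({"n_components": k, "cv_accuracy": acc})
            if best is None or acc > best[1]:
                best = (k, acc)
        res = SelectionResult("pca", best[0], pd.DataFrame(rows))
        res._scaler = scaler
        res._pca = PCA(n_components=best[0], random_state=seed).fit(Z)
        return res

    if method == "rfecv":
        remaining = list(X_frame.columns)
        order_removed: list[str] = []
        while len(remaining) > 1:
            model = make_classifier(classifier_id, seed=seed, **params)
            model.fit(X_frame[remaining].to_numpy(), y)
            imp = _rank_features(model, remaining)
            if imp is None:  # surrogate ranking for importance-free models
                from sklearn.linear_model import LogisticRegression

                surrogate = LogisticRegression(max_iter=2000)
                Z = StandardScaler().fit_transform(X_frame[remaining].to_numpy())
                surrogate.fit(Z, y)
                imp = np.abs(surrogate.coef_).ravel()
            worst = remaining[int(np.argmin(imp))]
            order_removed.append(worst)
            remaining = [c for c in remaining if c != worst]
        order_removed.append(remaining[0])
        # subset of size s = the s features removed last
        rows, best = [], None
        for s in range(1, p + 1):
            cols = order_removed[p - s :]
            acc = cv_with(cols)
            rows.append({"n_features": s, "cv_accuracy": acc})
            if best is None or acc > best[1]:
                best = (cols, acc)
        return SelectionResult("rfecv", sorted(best[0]), pd.DataFrame(rows))

    if method == "genetic_algorithm":
        cfg = ga_config or GAConfig(folds=folds, seed=seed)
        return ga_select(X_frame, y, classifier_id, params, cfg, use_taguchi)

    raise ValueError(f"unknown selection method {method!r}")


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ModelReport:
    classifier_id: str
    selection_method: str
    n_selected: int
    best_params: dict
    fold_metrics: pd.DataFrame  # repeat, fold, accuracy..auc
    cv_summary: pd.DataFrame  # per metric: mean, sd, ci_low, ci_high (two axes)
    test_metrics: dict[str, float]
    importances: pd.Series | None  # normalized, None if model exposes none


_METRICS = ("accuracy", "precision", "recall", "f1", "auc")


def _fold_metrics(y_true, y_pred, y_score) -> dict[str, float]:
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }
    out["auc"] = (
        roc_auc_score(y_true, y_score) if len(np.unique(y_true)) > 1 else np.nan
    )
    return out


def _ci(values: np.ndarray) -> tuple[float, float, float, float]:
    """mean, sd, and t-based 95% CI over k values."""
    k = len(values)
    m = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if k > 1 else 0.0
    if k > 1 and sd > 0:
        half = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
    else:
        half = 0.0
    return m, sd, m - half, m + half


def evaluate(
    train: CohortTable,
    test: CohortTable,
    classifier_id: str,
    selection: SelectionResult,
    best_params: Mapping | None = None,
    folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> ModelReport:
    """Repeated stratified k-fold CV on the training set plus a single
    held-out test evaluation.

    The CV summary carries both aggregation axes: per-repeat fold CIs
    (axis="folds", one row set per repeat) and the across-repeat CI of the
    repeat means (axis="repeats").
    """
    params = dict(best_params or {})
    Xtr_frame, ytr = _xy(train)
    Xte_frame, yte = _xy(test)
    Xtr = selection.transform(Xtr_frame)
    Xte = selection.transform(Xte_frame)

    rows = []
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(Xtr, ytr)):
            if len(np.unique(ytr[te])) < 2:
                logger.info("repeat %d fold %d skipped: single-class fold", r, f)
                continue
            model = make_classifier(classifier_id, seed=seed + r, **params)
            model.fit(Xtr[tr], ytr[tr])
            score = model.predict_proba(Xtr[te])[:, 1]
            pred = (score >= 0.5).astype(int)
            rows.append({"repeat": r, "fold": f, **_fold_metrics(ytr[te], pred, score)})
    fold_metrics = pd.DataFrame(rows)

    summary_rows = []
    for metric in _METRICS:
        per_repeat_means = fold_metrics.groupby("repeat")[metric].mean().to_numpy()
        m, sd, lo, hi = _ci(per_repeat_means)
        summary_rows.append(
            {"metric": metric, "axis": "repeats", "mean": m, "sd": sd,
             "ci_low": lo, "ci_high": hi}
        )
        m, sd, lo, hi = _ci(fold_metrics[metric].to_numpy())
        summary_rows.append(
            {"metric": metric, "axis": "folds", "mean": m, "sd": sd,
             "ci_low": lo, "ci_high": hi}
        )
    cv_summary = pd.DataFrame(summary_rows)

    final = make_classifier(classifier_id, seed=seed, **params)
    final.fit(Xtr, ytr)
    score = final.predict_proba(Xte)[:, 1]
    pred = (score >= 0.5).astype(int)
    test_metrics = _fold_metrics(yte, pred, score)

    imp = _rank_features(final, range(Xtr.shape[1]))
    importances = None
    if imp is not None and imp.sum() > 0 and selection.method != "pca":
        names = (
            selection.selected
            if isinstance(selection.selected, list)
            else list(Xtr_frame.columns)
        )
        importances = pd.Series(imp / imp.sum(), index=names).sort_index()

    return ModelReport(
        classifier_id=classifier_id,
        selection_method=selection.method,
        n_selected=selection.n_selected,
        best_params=params,
        fold_metrics=fold_metrics,
        cv_summary=cv_summary,
        test_metrics=test_metrics,
        importances=importances,
    )


def aggregate_importance(
    reports: Sequence[ModelReport], k: int = 3, top_n: int = 10
) -> pd.DataFrame:
    """Mean normalized feature importance across the k best models.

    Models are ranked by mean CV accuracy (repeats axis); models without
    importances (e.g. k-NN) are excluded with a log entry.  Returns the
    per-model and mean importances for the top_n features by mean, ties
    broken by feature name.
    """
    best_per_model: dict[str, tuple[float, ModelReport]] = {}
    for rep in reports:
        if rep.importances is None:
            logger.info("%s/%s excluded: no importances",
                        rep.classifier_id, rep.selection_method)
            continue
        acc = rep.cv_summary.query("metric == 'accuracy' and axis == 'repeats'")[
            "mean"
        ].iloc[0]
        prev = best_per_model.get(rep.classifier_id)
        if prev is None or acc > prev[0]:
            best_per_model[rep.classifier_id] = (acc, rep)
    usable = sorted(best_per_model.values(), key=lambda t: -t[0])
    top = [rep for _, rep in usable[:k]]
    if not top:
        raise ValueError("no reports with importances")
    frame = pd.DataFrame(
        {f"{rep.classifier_id}": rep.importances for rep in top}
    ).fillna(0.0)
    frame["mean_importance"] = frame.mean(axis=1)
    frame = frame.sort_values(
        ["mean_importance"], ascending=False, kind="stable"
    )
    frame = frame.loc[
        frame["mean_importance"]
        .rename("m")
        .reset_index()
        .sort_values(["m", "index"], ascending=[False, True], kind="stable")["index"]
    ]
    out = frame.head(top_n).reset_index(names="feature")
    return out
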