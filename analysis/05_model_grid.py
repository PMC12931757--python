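#!/usr/bin/env python
"""Feature-selection x classifier evaluation grid on the balanced cohort.

Stratified 80/20 split; per classifier: grid-search CV tuning, then each
selection strategy fitted on the training set only, then repeated
stratified 5-fold CV plus a held-out test evaluation.  The grid is written
in the familiar classifier x selection layout with the selected feature
counts.

Run 01 and 04 first.  The full eight-classifier grid with all five
strategies is expensive; the driver runs a representative subset by default
(edit CLASSIFIERS / SELECTIONS to widen it).
"""

import pathlib
import pickle

import pandas as pd

from mafldpred.data_model import default_schema, read_cohort_csv_indexed, write_report
from mafldpred.estimators import DEFAULT_GRIDS
from mafldpred.modeling import (
    GAConfig,
    evaluate,
    select_features,
    split_train_test,
    tune_classifier,
)

OUT = pathlib.Path("results/analysis")
DATA = pathlib.Path("scratch/analysis")
SEED = 20260301
CLASSIFIERS = (
    "logistic_regression",
    "k_nearest_neighbors",
    "decision_tree",
    "extra_trees",
    "extreme_gradient_boosting",
    "light_gradient_boosting",
)
SELECTIONS = ("none", "select_k_best", "pca", "rfecv", "genetic_algorithm")
N_REPEATS = 5

balanced = read_cohort_csv_indexed(DATA / "cohort_balanced.csv", default_schema())
train, test = split_train_test(balanced, 0.8, seed=SEED)

rows, reports = [], []
ga_cfg = GAConfig(population_size=12, n_generations=12, folds=3, seed=SEED, early_stop=5)
for cid in CLASSIFIERS:
    best, _ = tune_classifier(train, cid, DEFAULT_GRIDS[cid], folds=5, seed=SEED)
    for method in SELECTIONS:
        sel = select_features(
            train, method, classifier_id=cid, classifier_params=best,
            folds=3, seed=SEED, ga_config=ga_cfg, use_taguchi=False,
        )
        rep = evaluate(train, test, cid, sel, best, folds=5,
                       n_repeats=N_REPEATS, seed=SEED)
        reports.append(rep)
        acc = rep.cv_summary.query("metric=='accuracy' and axis=='repeats'").iloc[0]
        rows.append(
            {
                "classifier": cid,
                "selection": method,
                "n_features": rep.n_selected,
                "cv_accuracy": f"{acc['mean']:.3f} +- {acc['sd']:.3f}",
                "ci": f"[{acc['ci_low']:.3f}, {acc['ci_high']:.3f}]",
                "test_accuracy": round(rep.test_metrics["accuracy"], 3),
                "test_auc": round(rep.test_metrics["auc"], 3),
            }
        )
        print(rows[-1])

grid = pd.DataFrame(rows)
write_report(grid, OUT / "model_grid.csv")
with open(DATA / "model_reports.pkl", "wb") as fh:
    pickle.dump(reports, fh)

best_row = grid.sort_values("test_auc", ascending=False).iloc[0]
print(
    f"\nbest held-out AUC: {best_row['classifier']} / {best_row['selection']} "
    f"= {best_row['test_auc']}"
)
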