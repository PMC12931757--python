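#!/usr/bin/env python
"""Clean, impute, remove outliers, and balance the working cohort.

Cleaning: range filter, >45% feature / >50% row sparsity drops, dedupe,
with the 30/45/60% threshold sensitivity check.  The cohort is then imputed
with the benchmark winner (read from 03's report when present, chained
ridge otherwise), LOF-screened, and balanced by random undersampling; a
SMOTE-balanced variant is written alongside for comparison.

Run 01 (and optionally 03) first.
"""

import pathlib

import pandas as pd

from mafldpred.data_model import default_schema, read_cohort_csv_indexed, write_cohort_csv, write_report
from mafldpred.imputation import impute
from mafldpred.preprocessing import (
    apply_range_filter,
    balance_smote,
    balance_undersample,
    detect_outliers_lof,
    drop_sparse,
    remove_records,
    sensitivity_analysis,
)

OUT = pathlib.Path("results/analysis")
DATA = pathlib.Path("scratch/analysis")
SEED = 20260301
cohort = read_cohort_csv_indexed(DATA / "cohort.csv", default_schema())

cohort, range_rep = apply_range_filter(cohort)
cohort, sparse_rep = drop_sparse(cohort)
sens = sensitivity_analysis(cohort)
write_report(sens.table, OUT / "threshold_sensitivity.csv")
print(
    f"cleaning: {sum(range_rep.cells_nulled_by_range.values())} cells range-nulled, "
    f"{len(sparse_rep.features_dropped)} features and "
    f"{sparse_rep.rows_dropped_missing + sparse_rep.rows_dropped_duplicate} rows dropped"
)
if not sens.table.empty:
    print(
        f"threshold sensitivity: max SMD {sens.table['smd'].max():.4f}, "
        f"min KS p {sens.table['ks_p'].min():.2f}"
    )

bench_path = OUT / "imputation_benchmark.csv"
winner = "mice_ridge"
if bench_path.exists():
    summary = pd.read_csv(bench_path)
    summary = summary[summary["method"] != "mean_baseline"]
    winner = summary.sort_values("weighted_continuous", ascending=False)["method"].iloc[0]
print(f"imputing with {winner}")
cohort = impute(cohort, winner, seed=SEED)

flagged, scores = detect_outliers_lof(cohort, k_neighbors=20, score_threshold=1.5)
scores.to_frame().to_csv(DATA / "lof_scores.csv")
cohort = remove_records(cohort, flagged)
print(f"LOF flagged and removed {len(flagged)} records")

balanced = balance_undersample(cohort, seed=SEED)
write_cohort_csv(balanced, DATA / "cohort_balanced.csv")
smoted = balance_smote(cohort, k_neighbors=5, seed=SEED)
write_cohort_csv(smoted, DATA / "cohort_smote.csv")
counts = balanced.values["MAFLD"].value_counts()
print(
    f"undersampled to {balanced.n_records} records "
    f"({int(counts[0.0])}/{int(counts[1.0])}); SMOTE variant: {smoted.n_records}"
)
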