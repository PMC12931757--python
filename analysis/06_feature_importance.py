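#!/usr/bin/env python
"""Mean feature importance across the three best-performing models.

Aggregates the per-model normalized importances saved by 05_model_grid.py
and reports the ten features with the highest mean importance — the
screening variables a clinician would watch.

Run 05 first.
"""

import pathlib
import pickle

from mafldpred.data_model import write_report
from mafldpred.modeling import aggregate_importance

OUT = pathlib.Path("results/analysis")
DATA = pathlib.Path("scratch/analysis")
with open(DATA / "model_reports.pkl", "rb") as fh:
    reports = pickle.load(fh)

table = aggregate_importance(reports, k=3, top_n=10)
write_report(table, OUT / "feature_importance.csv")
print(table.to_string(index=False))
print(f"\nmost important predictor: {table['feature'].iloc[0]}")
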