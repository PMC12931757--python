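"""End-to-end pipeline: generate/ingest -> clean -> missingness diagnostics
-> imputation benchmark -> impute with the winner -> outlier removal ->
balance -> split -> select/tune/evaluate -> importance aggregation.

Every stage writes its report under the output directory and contributes a
content hash to the run manifest, so a rerun with the same configuration is
verifiably identical and each stage can be re-run from its predecessor's
serialized output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import imputation, mcar, modeling, preprocessing, synthetic
from .data_model import (
    CohortTable,
    default_schema,
    read_cohort_csv,
    summarize_by_group,
    write_cohort_csv,
    write_report,
)
from .estimators import OUTCOME_CLASSIFIERS, TINY_GRIDS

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Single structured configuration for the full run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # input: either a CSV path or a synthetic cohort
    input_csv: str | None = None
    n_records: int = 2000
    # cleaning
    feature_threshold: float = 0.45
    row_threshold: float = 0.50
    # imputation benchmark
    bench_methods: Sequence[str] = imputation.BENCHMARK_METHODS
    bench_seeds: Sequence[int] = (0, 1, 2, 3, 4)
    bench_folds: int = 3
    missingness_classifiers: Sequence[str] | None = None
    use_tiny_grids: bool = True
    min_complete: int = 100
    # outliers / balancing
    lof_k: int = 20
    lof_threshold: float = 1.5
    balancing: str = "undersample"  # or "smote"
    smote_k: int = 5
    # modeling
    classifiers: Sequence[str] = OUTCOME_CLASSIFIERS
    selection_methods: Sequence[str] = ("none", "select_k_best")
    folds: int = 5
    n_repeats: int = 3
    train_fraction: float = 0.8
    stages: Sequence[str] = (
        "ingest",
        "clean",
        "diagnose",
        "impute_bench",
        "impute",
        "outliers",
        "balance",
        "model",
        "importance",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _hash_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage error aborts with a :class:`StageError` naming the stage,
    after writing a partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": _config_dict(config)}
    stage_set = set(config.stages)
    table: CohortTable | None = None
    winner = "mice_ridge"
    reports: list[modeling.ModelReport] = []

    def record(stage: str, t0: float, **info) -> None:
        entry = {"seconds": round(time.time() - t0, 3), **info}
        if table is not None:
            entry["hash"] = _hash_frame(table.values)
            entry["shape"] = list(table.values.shape)
        manifest["stages"][stage] = entry
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    try:
        stage = "ingest"
        t0 = time.time()
        schema = default_schema()
        if config.input_csv:
            table, n_bad = read_cohort_csv(config.input_csv, schema)
            record(stage, t0, unparseable_cells=n_bad)
        else:
            sim_cfg = synthetic.CohortSimConfig(
                n_records=config.n_records, seed=config.seed
            )
            complete, cal_log = synthetic.generate_cohort(sim_cfg)
            miss_cfg = synthetic.MissingnessConfig(seed=config.seed)
            table, truth = synthetic.inject_missingness(complete, miss_cfg)
            write_report(cal_log, out / "calibration_log.csv")
            truth.to_csv(out / "injected_ground_truth.csv", index=False)
            record(stage, t0, synthetic=True)
        write_cohort_csv(table, out / "cohort_raw.csv")

        if "clean" in stage_set:
            stage = "clean"
            t0 = time.time()
            table, r1 = preprocessing.apply_range_filter(table)
            table, r2 = preprocessing.drop_sparse(
                table, config.feature_threshold, config.row_threshold
            )
            sens = preprocessing.sensitivity_analysis(table)
            write_report(sens.table, out / "sensitivity.csv")
            record(
                stage, t0,
                cells_nulled=sum(r1.cells_nulled_by_range.values()),
                features_dropped=list(r2.features_dropped),
                rows_dropped=r2.rows_dropped_missing + r2.rows_dropped_duplicate,
            )

        if "diagnose" in stage_set:
            stage = "diagnose"
            t0 = time.time()
            write_report(mcar.missingness_report(table), out / "missingness.csv")
            little = mcar.littles_mcar_test(table)
            write_report(
                {
                    "d2": little.d2,
                    "df": little.df,
                    "p_value": little.p_value,
                    "n_patterns": little.n_patterns,
                },
                out / "littles_test.json",
            )
            summary = summarize_by_group(table)
            write_report(summary, out / "group_summary.csv")
            record(stage, t0, d2=round(little.d2, 2), df=little.df)

        if "impute_bench" in stage_set:
            stage = "impute_bench"
            t0 = time.time()
            bench = imputation.run_benchmark(
                table,
                methods=config.bench_methods,
                seeds=config.bench_seeds,
                folds=config.bench_folds,
                grids=TINY_GRIDS if config.use_tiny_grids else None,
                classifier_ids=config.missingness_classifiers,
                min_complete=config.min_complete,
            )
            winner = bench.winner
            write_report(bench.summary, out / "imputation_benchmark.csv")
            record(stage, t0, winner=winner)

        if "impute" in stage_set:
            stage = "impute"
            t0 = time.time()
            table = imputation.impute(table, winner, seed=config.seed)
            record(stage, t0, method=winner)

        if "outliers" in stage_set:
            stage = "outliers"
            t0 = time.time()
            if table.mask.any().any():
                raise ValueError("outlier stage requires a complete table")
            flagged, scores = preprocessing.detect_outliers_lof(
                table, k_neighbors=config.lof_k, score_threshold=config.lof_threshold
            )
            scores.to_frame().to_csv(out / "lof_scores.csv")
            table = preprocessing.remove_records(table, flagged)
            record(stage, t0, n_outliers=len(flagged))

        if "balance" in stage_set:
            stage = "balance"
            t0 = time.time()
            if config.balancing == "smote":
                table = preprocessing.balance_smote(
                    table, k_neighbors=config.smote_k, seed=config.seed
                )
            else:
                table = preprocessing.balance_undersample(table, seed=config.seed)
            record(stage, t0, mode=config.balancing)

        if "model" in stage_set:
            stage = "model"
            t0 = time.time()
            if table.mask.any().any():
                raise ValueError("modeling requires a complete (imputed) table")
            train, test = modeling.split_train_test(
                table, config.train_fraction, seed=config.seed
            )
            grid_rows = []
            for cid in config.classifiers:
                best_params, _ = modeling.tune_classifier(
                    train, cid,
                    grid=TINY_GRIDS[cid] if config.use_tiny_grids else None,
                    folds=config.folds, seed=config.seed,
                )
                for method in config.selection_methods:
                    sel = modeling.select_features(
                        train, method, classifier_id=cid,
                        classifier_params=best_params,
                        folds=config.folds, seed=config.seed,
                        use_taguchi=False,
                    )
                    rep = modeling.evaluate(
                        train, test, cid, sel, best_params,
                        folds=config.folds, n_repeats=config.n_repeats,
                        seed=config.seed,
                    )
                    reports.append(rep)
                    acc = rep.cv_summary.query(
                        "metric=='accuracy' and axis=='repeats'"
                    ).iloc[0]
                    grid_rows.append(
                        {
                            "classifier": cid,
                            "selection": method,
                            "n_features": rep.n_selected,
                            "cv_accuracy_mean": acc["mean"],
                            "cv_accuracy_sd": acc["sd"],
                            "ci_low": acc["ci_low"],
                            "ci_high": acc["ci_high"],
                            "test_accuracy": rep.test_metrics["accuracy"],
                            "test_auc": rep.test_metrics["auc"],
                        }
                    )
            write_report(pd.DataFrame(grid_rows), out / "model_grid.csv")
            record(stage, t0, n_models=len(reports))

        if "importance" in stage_set and reports:
            stage = "importance"
            t0 = time.time()
            imp = modeling.aggregate_importance(reports)
            write_report(imp, out / "feature_importance.csv")
            record(stage, t0, top_feature=imp["feature"].iloc[0])
    except Exception as err:
        record(stage, time.time(), error=str(err))
        raise StageError(stage, err) from err

    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
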