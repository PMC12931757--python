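"""Cleaning, threshold sensitivity analysis, LOF outlier removal and class
balancing.

Cleaning order: range filter (out-of-range cells become missing), then
feature drop (missing fraction strictly above the feature threshold), then
row drop (missing fraction strictly above the row threshold over surviving
features), then exact-duplicate removal (first occurrence kept).  The
default thresholds — features > 45% missing, rows > 50% missing — are the
study's cutoffs; the sensitivity analysis reruns the cleaning at alternative
cutoffs and compares the surviving cohorts variable-by-variable with
standardized mean differences and two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .data_model import CohortTable, DegenerateGroupError

logger = logging.getLogger(__name__)


@dataclass
class CleaningReport:
    cells_nulled_by_range: dict[str, int] = field(default_factory=dict)
    features_dropped: dict[str, float] = field(default_factory=dict)
    rows_dropped_missing: int = 0
    rows_dropped_duplicate: int = 0
    final_shape: tuple[int, int] = (0, 0)


def apply_range_filter(table: CohortTable) -> tuple[CohortTable, CleaningReport]:
    """Null cells outside each continuous variable's acceptable range.

    The interval is closed: boundary values are retained.
    """
    values = table.values.copy()
    report = CleaningReport()
    for v in table.schema:
        if v.kind != "continuous" or v.acceptable_range is None:
            continue
        low, high = v.acceptable_range
        col = values[v.name]
        bad = col.notna() & ((col < low) | (col > high))
        if bad.any():
            report.cells_nulled_by_range[v.name] = int(bad.sum())
            values.loc[bad, v.name] = np.nan
    out = CohortTable(list(table.schema), values)
    report.final_shape = out.values.shape
    return out, report


class EmptyOutputError(ValueError):
    pass


def drop_sparse(
    table: CohortTable,
    feature_threshold: float = 0.45,
    row_threshold: float = 0.50,
) -> tuple[CohortTable, CleaningReport]:
    """Drop overly sparse features, then sparse rows, then duplicates.

    Both thresholds are *strict*: a feature at exactly the feature threshold
    survives.  Row missingness is computed over the surviving features
    (target excluded); duplicate detection compares all surviving columns
    with NaNs comparing equal.
    """
    if not (0 < feature_threshold < 1 and 0 < row_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    report = CleaningReport()
    frac = table.mask.mean(axis=0)
    target = table.target_name
    drop_feats = [
        c for c in table.values.columns if c != target and frac[c] > feature_threshold
    ]
    for c in drop_feats:
        report.features_dropped[c] = float(frac[c])
    schema = [v for v in table.schema if v.name not in drop_feats]
    values = table.values.drop(columns=drop_feats)
    if not any(v.role == "feature" for v in schema):
        raise EmptyOutputError("all features dropped")

    feat_cols = [v.name for v in schema if v.role == "feature"]
    row_frac = values[feat_cols].isna().mean(axis=1)
    keep = row_frac <= row_threshold
    report.rows_dropped_missing = int((~keep).sum())
    values = values[keep]

    dup = values.duplicated(keep="first")
    report.rows_dropped_duplicate = int(dup.sum())
    values = values[~dup]

    out = CohortTable(schema, values.copy())
    report.final_shape = out.values.shape
    return out, report


@dataclass
class SensitivityReport:
    """Pairwise cohort comparisons across cleaning-threshold scenarios."""

    table: pd.DataFrame  # scenario_a, scenario_b, variable, smd, ks_p


def smd(x1: np.ndarray, x2: np.ndarray) -> float:
    """Standardized mean difference |m1 - m2| / sqrt((s1^2 + s2^2)/2)."""
    m1, m2 = np.mean(x1), np.mean(x2)
    s1, s2 = np.std(x1, ddof=1), np.std(x2, ddof=1)
    denom = np.sqrt((s1**2 + s2**2) / 2)
    if denom == 0:
        return 0.0 if m1 == m2 else np.inf
    return float(abs(m1 - m2) / denom)


def sensitivity_analysis(
    table: CohortTable,
    thresholds: tuple[float, ...] = (0.30, 0.45, 0.60),
) -> SensitivityReport:
    """Rerun `drop_sparse` at each feature threshold and compare the
    surviving cohorts pairwise (SMD and two-sample KS p per shared
    continuous variable, on observed values)."""
    if len(thresholds) < 2:
        raise ValueError("need at least two threshold scenarios")
    cohorts: dict[float, CohortTable] = {}
    for thr in thresholds:
        cleaned, _ = drop_sparse(table, feature_threshold=thr)
        if cleaned.n_records < 2:
            logger.info("scenario %.2f skipped: <2 records", thr)
            continue
        cohorts[thr] = cleaned
    rows = []
    for a, b in combinations(sorted(cohorts), 2):
        ta, tb = cohorts[a], cohorts[b]
        shared = [
            v.name
            for v in ta.schema
            if v.kind == "continuous" and any(w.name == v.name for w in tb.schema)
        ]
        for name in shared:
            xa = ta.values[name].dropna().to_numpy()
            xb = tb.values[name].dropna().to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            if len(xa) == len(xb) and np.array_equal(np.sort(xa), np.sort(xb)):
                d, ksp = 0.0, 1.0  # identical surviving cohorts
            else:
                d = smd(xa, xb)
                ksp = float(stats.ks_2samp(xa, xb).pvalue)
            rows.append(
                {"scenario_a": a, "scenario_b": b, "variable": name, "smd": d, "ks_p": ksp}
            )
    return SensitivityReport(
        pd.DataFrame(rows, columns=["scenario_a", "scenario_b", "variable", "smd", "ks_p"])
    )


# ---------------------------------------------------------------------------
# outliers


def detect_outliers_lof(
    table: CohortTable,
    k_neighbors: int = 20,
    score_threshold: float = 1.5,
    flag_fraction: float | None = None,
) -> tuple[pd.Index, pd.Series]:
    """Local-outlier-factor flags on standardized continuous features.

    The LOF score is the ratio of a point's neighbours' local density to its
    own; scores near 1 are inliers.  Records are flagged when their score
    exceeds ``score_threshold``, or — if ``flag_fraction`` is given — the
    top fraction of scores is flagged instead.  Requires a complete table
    (run after imputation so missingness cannot masquerade as isolation).
    """
    if table.mask.any().any():
        raise ValueError("LOF requires a complete table (impute first)")
    n = table.n_records
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n={n}")
    cont = [v.name for v in table.schema if v.kind == "continuous"]
    X = StandardScaler().fit_transform(table.values[cont].to_numpy())
    lof = LocalOutlierFactor(n_neighbors=k_neighbors)
    lof.fit(X)
    scores = pd.Series(-lof.negative_outlier_factor_, index=table.record_ids, name="lof")
    if flag_fraction is not None:
        k = int(round(flag_fraction * n))
        flagged = scores.sort_values(ascending=False).index[:k]
    else:
        flagged = scores.index[scores > score_threshold]
    return flagged, scores


def remove_records(table: CohortTable, record_ids: pd.Index) -> CohortTable:
    keep = table.record_ids.difference(record_ids)
    return table.subset(keep)


# ---------------------------------------------------------------------------
# class balancing


def balance_undersample(table: CohortTable, seed: int = 0) -> CohortTable:
    """Randomly downsample the majority class to the minority count."""
    target = table.target_name
    y = table.values[target]
    counts = y.value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise DegenerateGroupError("both classes must be non-empty")
    minority = counts.idxmin()
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for cls, grp in table.values.groupby(y, sort=True):
        ids = grp.index.to_numpy()
        if cls == minority or len(ids) == n_min:
            keep.append(ids)
        else:
            keep.append(rng.choice(ids, size=n_min, replace=False))
    kept = np.concatenate(keep)
    return table.subset(np.sort(kept))


def balance_smote(
    table: CohortTable, k_neighbors: int = 5, seed: int = 0
) -> CohortTable:
    """Synthetic minority oversampling by convex interpolation.

    Each synthetic record is drawn on the segment between a random minority
    record and one of its k nearest minority neighbours (Euclidean distance
    on standardized features); binary features are set by nearest-endpoint
    rounding.  Classes end up exactly equal.
    """
    target = table.target_name
    y = table.values[target]
    counts = y.value_counts()
    if len(counts) < 2:
        raise DegenerateGroupError("both classes must be present")
    minority = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return table.copy()
    if table.mask.any().any():
        raise ValueError("SMOTE requires a complete table")
    min_rows = table.values[y == minority]
    if len(min_rows) <= k_neighbors:
        raise ValueError(
            f"minority count {len(min_rows)} must exceed k_neighbors={k_neighbors}"
        )
    feat_cols = [c for c in table.values.columns if c != target]
    scaler = StandardScaler().fit(min_rows[feat_cols].to_numpy())
    Z = scaler.transform(min_rows[feat_cols].to_numpy())
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Z)
    _, nbr = nn.kneighbors(Z)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, len(min_rows), size=n_needed)
    nbr_pick = rng.integers(1, k_neighbors + 1, size=n_needed)
    lam = rng.random(n_needed)
    X = min_rows[feat_cols].to_numpy()
    partner = nbr[base_idx, nbr_pick]
    synth = X[base_idx] + lam[:, None] * (X[partner] - X[base_idx])

    schema_map = {v.name: v for v in table.schema}
    synth_frame = pd.DataFrame(synth, columns=feat_cols)
    for j, c in enumerate(feat_cols):
        if schema_map[c].kind == "binary":
            # nearest endpoint along the interpolation
            synth_frame[c] = np.where(lam < 0.5, X[base_idx, j], X[partner, j])
    synth_frame[target] = float(minority)
    start = int(pd.to_numeric(table.record_ids, errors="coerce").max()) + 1
    synth_frame.index = pd.RangeIndex(start, start + n_needed, name="record_id")
    values = pd.concat([table.values, synth_frame[table.values.columns]])
    return CohortTable(list(table.schema), values)
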