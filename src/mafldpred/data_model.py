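"""Variable schema, cohort container, CSV I/O and descriptive group summaries.

The cohort is a rectangular table of clinical variables measured on type-2
diabetes patients, with a binary MAFLD (metabolic-associated fatty liver
disease) target.  Missing cells are carried explicitly: ``CohortTable.values``
holds NaN where a cell is missing and ``CohortTable.mask`` is the congruent
boolean missingness indicator (True = missing).

Group summaries mirror the usual "Table 1" of a clinical paper: per continuous
variable the class-conditional mean and quartiles with a Kruskal-Wallis
group-comparison p-value (the variables are not normally distributed, which a
Shapiro-Wilk p accompanies), and per binary variable class-conditional
counts/percentages with a chi-square p-value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats


class SchemaMismatchError(ValueError):
    """A required schema variable is absent from the input header."""


class EmptyInputError(ValueError):
    """The input contains no data rows."""


class DegenerateGroupError(ValueError):
    """A target class contains zero records."""


#: cell tokens treated as missing on read (case-insensitive)
MISSING_TOKENS = {"", "na", "nan"}


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single cohort variable.

    Parameters
    ----------
    name:
        Column identifier, unique within a schema.
    kind:
        ``"continuous"`` or ``"binary"``.
    units:
        Free-text measurement units (e.g. ``"U/L"``); empty for unitless.
    acceptable_range:
        Closed plausibility interval ``(low, high)`` for continuous
        variables; values outside are physiologically impossible and are
        nulled by the range filter.
    positive_label:
        Meaning of code 1 for binary variables (e.g. ``"female"``).
    role:
        ``"feature"`` or ``"target"``.
    """

    name: str
    kind: Literal["continuous", "binary"]
    units: str = ""
    acceptable_range: tuple[float, float] | None = None
    positive_label: str | None = None
    role: Literal["feature", "target"] = "feature"

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.acceptable_range is not None:
                low, high = self.acceptable_range
                if not low < high:
                    raise ValueError(
                        f"{self.name}: acceptable_range must satisfy low < high"
                    )
        if self.role == "target" and self.kind != "binary":
            raise ValueError(f"{self.name}: target variable must be binary")


def validate_schema(schema: Sequence[VariableSchema]) -> None:
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        raise ValueError("schema variable names must be unique")
    targets = [v for v in schema if v.role == "target"]
    if len(targets) > 1:
        raise ValueError("schema must declare at most one target variable")


@dataclass
class CohortTable:
    """Records x variables table with an explicit missingness mask.

    ``values`` is a float DataFrame (NaN = missing) whose columns follow the
    schema order; the index provides stable record identifiers.
    """

    schema: list[VariableSchema]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        validate_schema(self.schema)
        cols = [v.name for v in self.schema]
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise SchemaMismatchError(f"columns absent from data: {missing}")
        self.values = self.values[cols].astype(float)
        for v in self.schema:
            if v.kind == "binary":
                col = self.values[v.name].dropna()
                bad = ~col.isin([0.0, 1.0])
                if bad.any():
                    raise ValueError(
                        f"binary variable {v.name} has non-0/1 values"
                    )

    # -- basic accessors -------------------------------------------------

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator, True where a cell is missing."""
        return self.values.isna()

    @property
    def record_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def target_name(self) -> str | None:
        for v in self.schema:
            if v.role == "target":
                return v.name
        return None

    @property
    def feature_names(self) -> list[str]:
        return [v.name for v in self.schema if v.role == "feature"]

    def variable(self, name: str) -> VariableSchema:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def subset(self, record_ids: Iterable) -> "CohortTable":
        return CohortTable(self.schema, self.values.loc[list(record_ids)].copy())

    def copy(self) -> "CohortTable":
        return CohortTable(list(self.schema), self.values.copy())

    def missing_fraction(self) -> pd.Series:
        """Per-variable missing fraction."""
        return self.mask.mean(axis=0)


# ---------------------------------------------------------------------------
# schema config I/O


def schema_to_config(schema: Sequence[VariableSchema]) -> list[dict]:
    out = []
    for v in schema:
        d: dict = {"name": v.name, "kind": v.kind, "role": v.role}
        if v.units:
            d["units"] = v.units
        if v.acceptable_range is not None:
            d["range"] = list(v.acceptable_range)
        if v.positive_label is not None:
            d["positive_label"] = v.positive_label
        out.append(d)
    return out


def schema_from_config(entries: Iterable[dict]) -> list[VariableSchema]:
    schema = []
    for d in entries:
        rng = d.get("range")
        schema.append(
            VariableSchema(
                name=d["name"],
                kind=d["kind"],
                units=d.get("units", ""),
                acceptable_range=tuple(rng) if rng is not None else None,
                positive_label=d.get("positive_label"),
                role=d.get("role", "feature"),
            )
        )
    validate_schema(schema)
    return schema


def load_schema_yaml(path: str | Path) -> list[VariableSchema]:
    with open(path) as fh:
        return schema_from_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# the default 31-variable T2DM/MAFLD schema

# Acceptable ranges are broad physiologic-plausibility bounds (the range
# filter nulls impossible entries such as negative enzyme levels); they are a
# configuration default, not a clinical reference interval.
_CONTINUOUS = [
    # name, units, (low, high)
    ("Age", "years", (20.0, 110.0)),
    ("ALKP", "U/L", (10.0, 3000.0)),
    ("ALT", "U/L", (1.0, 3000.0)),
    ("AST", "U/L", (1.0, 3000.0)),
    ("BMI", "kg/m2", (10.0, 80.0)),
    ("Chl", "mg/dL", (50.0, 600.0)),
    ("Cr", "mg/dL", (0.2, 15.0)),
    ("CRP", "mg/L", (0.0, 300.0)),
    ("DBP", "mmHg", (30.0, 150.0)),
    ("DDM", "years", (0.0, 70.0)),
    ("FBS", "mg/dL", (40.0, 700.0)),
    ("HBA1C", "%", (3.0, 20.0)),
    ("HDL", "mg/dL", (10.0, 150.0)),
    ("Height", "cm", (120.0, 220.0)),
    ("Hip", "cm", (50.0, 200.0)),
    ("HOMA", "", (0.0, 60.0)),
    ("2HPP", "mg/dL", (40.0, 800.0)),
    ("Insulin", "uIU/mL", (0.1, 200.0)),
    ("LDL", "mg/dL", (10.0, 400.0)),
    ("PLT", "1000 cells/uL", (10.0, 1500.0)),
    ("Tg", "mg/dL", (20.0, 2000.0)),
    ("UA", "mg/dL", (1.0, 20.0)),
    ("VitD", "ng/mL", (1.0, 150.0)),
    ("Waist", "cm", (40.0, 200.0)),
    ("Weight", "kg", (30.0, 250.0)),
]

_BINARY = [
    ("Sex", "female"),
    ("CAD", "present"),
    ("CVA", "present"),
    ("HTN", "present"),
    ("Retino", "present"),
    ("Smoking", "current smoker"),
]


def default_schema() -> list[VariableSchema]:
    """The 31 predictors (25 continuous, 6 binary) plus the MAFLD target."""
    schema = [
        VariableSchema(name, "continuous", units, rng)
        for name, units, rng in _CONTINUOUS
    ]
    schema += [
        VariableSchema(name, "binary", positive_label=lbl) for name, lbl in _BINARY
    ]
    schema.append(
        VariableSchema("MAFLD", "binary", positive_label="MAFLD", role="target")
    )
    validate_schema(schema)
    return schema


# ---------------------------------------------------------------------------
# CSV ingestion


def read_cohort_csv(
    path: str | Path, schema: Sequence[VariableSchema]
) -> tuple[CohortTable, int]:
    """Read a cohort CSV against a schema.

    Empty cells and the tokens in :data:`MISSING_TOKENS` become missing;
    any other unparseable cell also becomes missing and is counted in the
    returned warning tally.

    Returns
    -------
    (table, n_unparseable)
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    names = [v.name for v in schema]
    absent = [n for n in names if n not in raw.columns]
    if absent:
        raise SchemaMismatchError(f"{path}: columns missing from header: {absent}")

    values = {}
    n_unparseable = 0
    for name in names:
        col = raw[name].str.strip()
        is_token = col.str.lower().isin(MISSING_TOKENS)
        parsed = pd.to_numeric(col, errors="coerce")
        bad = parsed.isna() & ~is_token
        n_unparseable += int(bad.sum())
        parsed[is_token | bad] = np.nan
        values[name] = parsed
    frame = pd.DataFrame(values)
    if n_unparseable:
        warnings.warn(
            f"{path}: {n_unparseable} unparseable cell(s) treated as missing",
            stacklevel=2,
        )
    return CohortTable(list(schema), frame), n_unparseable


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    table.values.to_csv(path, index_label="record_id")


def read_cohort_csv_indexed(
    path: str | Path, schema: Sequence[VariableSchema]
) -> CohortTable:
    """Read a CSV previously written by :func:`write_cohort_csv`."""
    frame = pd.read_csv(path, index_col="record_id")
    return CohortTable(list(schema), frame)


# ---------------------------------------------------------------------------
# group summaries


@dataclass
class GroupSummary:
    """Class-conditional descriptives with group-comparison tests."""

    continuous: pd.DataFrame = field(default_factory=pd.DataFrame)
    binary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _kruskal_p(groups: list[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # all ties: no evidence of a group difference
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def _chi2_p(counts: np.ndarray) -> tuple[float, float]:
    # degenerate margins carry no information; report p = 1
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def _shapiro_p(x: np.ndarray, max_n: int = 5000) -> float:
    if len(x) < 3 or np.all(x == x[0]):
        return np.nan
    if len(x) > max_n:  # Shapiro-Wilk is defined for moderate n; subsample
        rng = np.random.default_rng(0)
        x = rng.choice(x, size=max_n, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def summarize_by_group(table: CohortTable) -> GroupSummary:
    """Per-variable class-conditional descriptives (clinical "Table 1" layout).

    Continuous variables: mean, Q1, Q3 per class (linear-interpolation
    quartiles), Kruskal-Wallis p across classes, Shapiro-Wilk normality p.
    Binary variables: positive count and percentage per class, chi-square p
    (no continuity correction; degenerate margins give p = 1).
    """
    tname = table.target_name
    if tname is None:
        raise ValueError("cohort has no target variable")
    y = table.values[tname]
    if y.isna().any():
        raise ValueError("target column must be complete")
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise DegenerateGroupError("need two target classes")
    for c in classes:
        if (y == c).sum() == 0:
            raise DegenerateGroupError(f"class {c} has zero records")

    cont_rows, bin_rows = [], []
    for v in table.schema:
        if v.role == "target":
            continue
        col = table.values[v.name]
        if v.kind == "continuous":
            groups = [col[y == c].dropna().to_numpy() for c in classes]
            stat, p = _kruskal_p([g for g in groups if len(g)])
            row = {"variable": v.name, "units": v.units}
            for c, g in zip(classes, groups):
                lbl = int(c)
                row[f"mean_{lbl}"] = float(np.mean(g)) if len(g) else np.nan
                row[f"q1_{lbl}"] = float(np.percentile(g, 25)) if len(g) else np.nan
                row[f"q3_{lbl}"] = float(np.percentile(g, 75)) if len(g) else np.nan
            row["p_value"] = p
            row["normality_p"] = _shapiro_p(col.dropna().to_numpy())
            cont_rows.append(row)
        else:
            obs = col.dropna()
            yobs = y[obs.index]
            counts = np.array(
                [
                    [(obs[yobs == c] == 0).sum(), (obs[yobs == c] == 1).sum()]
                    for c in classes
                ]
            )
            stat, p = _chi2_p(counts)
            row = {"variable": v.name, "positive_label": v.positive_label or "1"}
            for i, c in enumerate(classes):
                lbl = int(c)
                n_pos = int(counts[i, 1])
                n_tot = int(counts[i].sum())
                row[f"n_pos_{lbl}"] = n_pos
                row[f"pct_pos_{lbl}"] = 100.0 * n_pos / n_tot if n_tot else np.nan
            row["p_value"] = p
            bin_rows.append(row)
    return GroupSummary(pd.DataFrame(cont_rows), pd.DataFrame(bin_rows))


# ---------------------------------------------------------------------------
# report writing


def write_report(obj, path: str | Path) -> list[Path]:
    """Serialize a report object to deterministic CSV/JSON artifacts.

    ``GroupSummary`` -> two CSVs (continuous/binary); a DataFrame -> one CSV;
    a dict/list -> one JSON file.  Returns the paths written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(obj, GroupSummary):
        for part, frame in (("continuous", obj.continuous), ("binary", obj.binary)):
            p = path.with_name(f"{path.stem}_{part}.csv")
            frame.to_csv(p, index=False)
            written.append(p)
    elif isinstance(obj, pd.DataFrame):
        p = path if path.suffix == ".csv" else path.with_suffix(".csv")
        obj.to_csv(p, index=False)
        written.append(p)
    else:
        p = path if path.suffix == ".json" else path.with_suffix(".json")
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        written.append(p)
    return written


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
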