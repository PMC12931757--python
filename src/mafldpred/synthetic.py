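"""Synthetic T2DM cohort generator calibrated to published class-conditional
descriptives, plus a configurable MCAR/MAR missingness injector.

Continuous variables are drawn from class-conditional *shifted log-normal*
distributions ``X = c + exp(mu + sigma * Z)``; the three parameters are solved
numerically so that the population mean, Q1 and Q3 hit the configured targets
(clinical lab variables are right-skewed and non-normal, which this family
captures while admitting an exact moment/quantile solution).  A handful of
target triples imply left skew (mean below the implied median); those have no
solution in this family and fall back to matching mean and Q3 only at a fixed
mild sigma — the fallback is recorded in the calibration log.

Cross-variable dependence is imposed through a Gaussian copula: one latent
standard-normal vector per record with a configurable correlation matrix,
mapped through each margin's quantile function (continuous) or thresholded at
the class rate (binary).

Missingness injection supports MCAR (independent Bernoulli per cell) and MAR
(per-column logistic model on a set of always-observed driver columns, with an
*exact* count of ``round(rate * n)`` cells masked by probability-weighted
sampling).  Six variables — sex, age, height, weight, DBP and BMI — are always
complete, matching the structure of routine clinical exports where demographics
and vitals are recorded at every visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr

from .data_model import CohortTable, VariableSchema, default_schema

_Z25 = 0.6744897501960817  # standard-normal upper quartile


class CalibrationError(ValueError):
    """No (mean, Q1, Q3) solution exists for a variable's targets."""


class InvalidDriverError(ValueError):
    """A MAR driver column itself receives injected missingness."""


# ---------------------------------------------------------------------------
# published class-conditional targets: {variable: (class0, class1)} with
# (mean, Q1, Q3) per class for continuous and positive rate per class for
# binary variables.  Class 1 = MAFLD.

CONTINUOUS_TARGETS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "Age": ((60.4, 53, 68), (55.3, 47, 64)),
    "ALKP": ((146.6, 100, 173), (162.9, 112, 200)),
    "ALT": ((21.5, 15, 25), (38, 24.5, 48)),
    "AST": ((19.2, 15, 22), (28, 19, 33)),
    "BMI": ((28.5, 25.1, 31.2), (31.1, 27.2, 34.3)),
    "Chl": ((171.4, 140, 198.5), (181.1, 148, 208)),
    "Cr": ((1, 0.8, 1.1), (1, 0.9, 1.1)),
    "CRP": ((1.4, 1, 1.4), (1.8, 1, 1.9)),
    "DBP": ((76.8, 70, 80), (79, 75, 80)),
    "DDM": ((11.4, 4, 17), (10.3, 4, 15)),
    "FBS": ((157.5, 121.5, 182), (158.1, 121, 179.5)),
    "HBA1C": ((7.6, 6.5, 8.5), (7.6, 6.5, 8.5)),
    "HDL": ((44.9, 37, 52), (43.9, 37, 50)),
    "Height": ((163.3, 156, 170), (165.2, 158, 173)),
    "Hip": ((104.7, 100, 109), (109, 102, 114)),
    "HOMA": ((3.8, 2.5, 4.5), (4.6, 2.8, 5.5)),
    "2HPP": ((210.9, 154.5, 250), (213.3, 150, 255)),
    "Insulin": ((9.7, 8, 10.3), (12.1, 8.1, 14)),
    "LDL": ((95.6, 71, 117), (102, 77, 124)),
    "PLT": ((247.5, 226.1, 267.8), (266.9, 249.3, 295)),
    "Tg": ((160.7, 103.5, 195), (182.6, 115, 226)),
    "UA": ((5, 4, 5.6), (5.3, 4.2, 6)),
    "VitD": ((26.9, 20, 30), (23.5, 16.1, 28.1)),
    "Waist": ((98.1, 91, 103), (103.2, 96, 110)),
    "Weight": ((75.8, 67, 83), (84.8, 73, 94)),
}

BINARY_RATES: dict[str, tuple[float, float]] = {
    "Sex": (0.490, 0.584),  # positive = female
    "CAD": (0.122, 0.099),
    "CVA": (0.011, 0.006),
    "HTN": (0.213, 0.189),
    "Retino": (0.060, 0.044),
    "Smoking": (0.019, 0.016),
}

#: class-1 (MAFLD) fraction before balancing: 1827 of 3740 records
DEFAULT_PREVALENCE = 1827 / 3740

ALWAYS_COMPLETE = ("Sex", "Age", "Height", "Weight", "DBP", "BMI")

# Per-column missingness rates for the 25 variables that carry missing data.
# The published per-column percentages are not reproducible without the
# clinical export; these defaults emulate a routine-care pattern in which
# specialised labs (insulin/HOMA, inflammation, vitamin D) are ordered far
# less often than core chemistry.  All rates are overridable.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "Insulin": 0.40,
    "HOMA": 0.40,
    "CRP": 0.32,
    "VitD": 0.30,
    "2HPP": 0.25,
    "Waist": 0.22,
    "Hip": 0.22,
    "ALKP": 0.18,
    "UA": 0.15,
    "PLT": 0.12,
    "AST": 0.10,
    "ALT": 0.10,
    "HDL": 0.10,
    "LDL": 0.10,
    "Chl": 0.08,
    "Tg": 0.08,
    "Cr": 0.06,
    "FBS": 0.05,
    "HBA1C": 0.05,
    "DDM": 0.12,
    "CAD": 0.08,
    "CVA": 0.08,
    "HTN": 0.06,
    "Retino": 0.10,
    "Smoking": 0.12,
}


def default_correlation(names: Sequence[str]) -> pd.DataFrame:
    """Default latent (copula) correlation.

    0.6 among anthropometrics, 0.5 between the two aminotransferases, 0.3
    among lipids, 0 elsewhere; positive definite by block structure.
    """
    R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    blocks = [
        (["Weight", "BMI", "Waist", "Hip"], 0.6),
        (["ALT", "AST"], 0.5),
        (["Chl", "HDL", "LDL", "Tg"], 0.3),
    ]
    for group, rho in blocks:
        present = [g for g in group if g in R.index]
        for a in present:
            for b in present:
                if a != b:
                    R.loc[a, b] = rho
    return R


# ---------------------------------------------------------------------------
# margin calibration


@dataclass(frozen=True)
class LognormalParams:
    shift: float
    mu: float
    sigma: float
    exact: bool  # False when only mean and Q3 were matched

    def quantile(self, z: np.ndarray) -> np.ndarray:
        """Value at the standard-normal latent score ``z``."""
        return self.shift + np.exp(self.mu + self.sigma * z)

    @property
    def mean(self) -> float:
        return self.shift + float(np.exp(self.mu + self.sigma**2 / 2))


def solve_shifted_lognormal(
    mean: float, q1: float, q3: float, fallback_sigma: float = 0.3
) -> LognormalParams:
    """Solve (shift, mu, sigma) so the shifted log-normal hits mean/Q1/Q3.

    The skew ratio r = (mean - Q1)/(Q3 - Q1) determines sigma alone; r > 1/2
    (right skew) admits an exact solution.  Otherwise only mean and Q3 are
    matched at a fixed mild sigma (requires mean < Q3).
    """
    if not q1 < q3:
        raise CalibrationError(f"need Q1 < Q3, got ({q1}, {q3})")
    r = (mean - q1) / (q3 - q1)

    def skew_ratio(s: float) -> float:
        return (np.exp(s**2 / 2) - np.exp(-_Z25 * s)) / (
            np.exp(_Z25 * s) - np.exp(-_Z25 * s)
        )

    if r > 0.5 + 1e-9:
        hi = 1.0
        while skew_ratio(hi) < r:
            hi *= 2
            if hi > 64:
                raise CalibrationError(f"skew ratio {r:.3f} unattainable")
        sigma = brentq(lambda s: skew_ratio(s) - r, 1e-9, hi, xtol=1e-12)
        emu = (q3 - q1) / (np.exp(_Z25 * sigma) - np.exp(-_Z25 * sigma))
        mu = float(np.log(emu))
        shift = q1 - emu * np.exp(-_Z25 * sigma)
        return LognormalParams(float(shift), mu, float(sigma), exact=True)

    # left-skew targets: match mean and Q3 only
    s = fallback_sigma
    denom = np.exp(_Z25 * s) - np.exp(s**2 / 2)
    if mean >= q3 or denom <= 0:
        raise CalibrationError(
            f"no fallback solution for (mean={mean}, q1={q1}, q3={q3})"
        )
    emu = (q3 - mean) / denom
    mu = float(np.log(emu))
    shift = mean - emu * np.exp(s**2 / 2)
    return LognormalParams(float(shift), mu, float(s), exact=False)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortSimConfig:
    """Generator configuration; defaults reproduce the published cohort
    structure (class-conditional descriptives, pre-balancing prevalence)."""

    n_records: int = 3740
    prevalence: float = DEFAULT_PREVALENCE
    continuous_targets: Mapping[str, tuple] = field(
        default_factory=lambda: dict(CONTINUOUS_TARGETS)
    )
    binary_rates: Mapping[str, tuple] = field(
        default_factory=lambda: dict(BINARY_RATES)
    )
    correlation: pd.DataFrame | None = None
    schema: list[VariableSchema] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


def generate_cohort(
    config: CohortSimConfig,
) -> tuple[CohortTable, pd.DataFrame]:
    """Draw a complete synthetic cohort.

    Returns the cohort plus a calibration log (one row per variable x class:
    the fitted margin parameters and whether the fit was exact).
    """
    schema = config.schema or default_schema()
    feature_names = [v.name for v in schema if v.role == "feature"]
    target = [v.name for v in schema if v.role == "target"][0]
    rng = np.random.default_rng(config.seed)

    n = config.n_records
    n1 = int(round(config.prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    R = config.correlation
    if R is None:
        R = default_correlation(feature_names)
    R = R.loc[feature_names, feature_names].to_numpy()
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    L = np.linalg.cholesky(R)  # raises if not positive definite
    Z = rng.standard_normal((n, len(feature_names))) @ L.T

    # solve margins per class once
    log_rows = []
    params: dict[str, list[LognormalParams]] = {}
    for name in feature_names:
        var = next(v for v in schema if v.name == name)
        if var.kind != "continuous":
            continue
        per_class = []
        for cls in (0, 1):
            m, q1, q3 = config.continuous_targets[name][cls]
            try:
                p = solve_shifted_lognormal(m, q1, q3)
            except CalibrationError as err:
                raise CalibrationError(f"{name} (class {cls}): {err}") from err
            per_class.append(p)
            log_rows.append(
                {
                    "variable": name,
                    "class": cls,
                    "shift": p.shift,
                    "mu": p.mu,
                    "sigma": p.sigma,
                    "exact_fit": p.exact,
                }
            )
        params[name] = per_class

    columns: dict[str, np.ndarray] = {}
    for j, name in enumerate(feature_names):
        var = next(v for v in schema if v.name == name)
        z = Z[:, j]
        if var.kind == "continuous":
            x = np.where(
                labels == 1,
                params[name][1].quantile(z),
                params[name][0].quantile(z),
            )
            if var.acceptable_range is not None:
                x = np.clip(x, *var.acceptable_range)
            columns[name] = x
        else:
            r0, r1 = config.binary_rates[name]
            u = ndtr(z)
            rate = np.where(labels == 1, r1, r0)
            columns[name] = (u < rate).astype(float)
    columns[target] = labels.astype(float)

    frame = pd.DataFrame(columns, index=pd.RangeIndex(n, name="record_id"))
    return CohortTable(list(schema), frame), pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# missingness injection


@dataclass
class MissingnessConfig:
    mechanism: str = "MAR"  # "MCAR" or "MAR"
    rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    always_complete: tuple[str, ...] = ALWAYS_COMPLETE
    #: per target column: (intercept, {driver column: weight}); drivers are
    #: z-scored before entering the logistic model
    mar_drivers: Mapping[str, tuple[float, Mapping[str, float]]] | None = None
    #: SD of a per-record latent "workup completeness" effect shared by all
    #: columns under MAR; induces the panel-wise co-missingness of real
    #: clinical exports (labs ordered together) and thereby preserves a
    #: sizeable fully observed subset.  Independent of the data values.
    panel_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for col, rate in self.rates.items():
            if not 0 <= rate < 1:
                raise ValueError(f"{col}: rate must lie in [0, 1)")
            if col in self.always_complete and rate > 0:
                raise ValueError(f"{col} is always complete but has rate {rate}")


def default_mar_drivers(
    rates: Mapping[str, float],
    slope_age: float = 2.0,
    slope_bmi: float = 1.0,
) -> dict[str, tuple[float, dict[str, float]]]:
    """Default MAR mechanism: older, heavier patients are likelier to lack
    specialised labs (their panels predate routine ordering of those tests)."""
    return {col: (0.0, {"Age": slope_age, "BMI": slope_bmi}) for col in rates}


def inject_missingness(
    table: CohortTable, config: MissingnessConfig
) -> tuple[CohortTable, pd.DataFrame]:
    """Mask cells in a complete cohort; returns (masked table, ground truth).

    Ground truth is a tidy frame of (record_id, variable, true_value) for
    every masked cell.  Under MAR exactly ``round(rate * n)`` cells per
    column are masked, sampled without replacement with probability weights
    from the column's logistic model on always-observed drivers.
    """
    if table.mask.any().any():
        raise ValueError("inject_missingness requires a complete table")
    rng = np.random.default_rng(config.seed)
    values = table.values.copy()
    n = len(values)
    truth_rows = []

    drivers = config.mar_drivers
    if config.mechanism == "MAR" and drivers is None:
        drivers = default_mar_drivers(config.rates)
    panel = (
        config.panel_sd * rng.standard_normal(n)
        if config.mechanism == "MAR" and config.panel_sd > 0
        else np.zeros(n)
    )

    for col in sorted(config.rates):
        rate = config.rates[col]
        if rate == 0 or col not in values.columns:
            continue
        if config.mechanism == "MCAR":
            hit = rng.random(n) < rate
            idx = values.index[hit]
        else:
            intercept, weights = drivers[col]
            for drv in weights:
                if config.rates.get(drv, 0) > 0:
                    raise InvalidDriverError(
                        f"driver {drv!r} for column {col!r} has injected missingness"
                    )
            eta = np.full(n, float(intercept)) + panel
            for drv, w in weights.items():
                x = values[drv].to_numpy()
                sd = x.std()
                zx = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
                eta = eta + w * zx
            p = expit(eta)
            k = int(round(rate * n))
            idx = values.index[
                rng.choice(n, size=k, replace=False, p=p / p.sum())
            ]
        for rid in idx:
            truth_rows.append(
                {"record_id": rid, "variable": col, "true_value": values.at[rid, col]}
            )
        values.loc[idx, col] = np.nan

    truth = pd.DataFrame(truth_rows, columns=["record_id", "variable", "true_value"])
    return CohortTable(list(table.schema), values), truth
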