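"""Missingness inventory, pattern extraction, and Little's MCAR test.

Little's test asks whether the data are Missing Completely At Random: it
groups records by missingness pattern, estimates the grand mean and
covariance by EM under a multivariate-normal model, and compares each
pattern's observed sub-mean against the EM grand mean with a chi-square
statistic

    d2 = sum_j  n_j (ybar_j - mu_j)' Sigma_j^{-1} (ybar_j - mu_j),

where the mean and covariance are restricted to pattern j's observed
variables; df = sum_j p_j - p.  Rejection argues against MCAR (and, with
MNAR ruled out on operational grounds, for MAR).  Binary variables enter as
0/1 numerics — an approximation shared by common implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortTable


class TestUndefinedError(ValueError):
    """Little's test needs at least two distinct missingness patterns."""


class SingularPatternError(ValueError):
    """A pattern's restricted covariance is singular."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, mean: np.ndarray, cov: np.ndarray):
        super().__init__(msg)
        self.mean = mean
        self.cov = cov


@dataclass(frozen=True)
class MissingnessPattern:
    observed_set: tuple[int, ...]  # indices of observed variables
    count: int
    row_indices: tuple[int, ...]


@dataclass(frozen=True)
class LittleTestResult:
    d2: float
    df: int
    p_value: float
    n_patterns: int
    em_mean: np.ndarray
    em_cov: np.ndarray


def extract_patterns(mask: np.ndarray | pd.DataFrame) -> list[MissingnessPattern]:
    """Distinct row missingness patterns, sorted by count descending.

    Counts partition the rows: they sum to n.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    n, p = mask.shape
    # encode each row pattern as bytes for grouping
    keys = np.packbits(mask, axis=1).tobytes()
    width = (p + 7) // 8
    groups: dict[bytes, list[int]] = {}
    for i in range(n):
        groups.setdefault(keys[i * width : (i + 1) * width], []).append(i)
    patterns = []
    for rows in groups.values():
        observed = tuple(np.flatnonzero(~mask[rows[0]]).tolist())
        patterns.append(
            MissingnessPattern(observed, len(rows), tuple(rows))
        )
    patterns.sort(key=lambda pt: (-pt.count, pt.observed_set))
    return patterns


# ---------------------------------------------------------------------------
# EM for the incomplete multivariate normal


def _observed_loglik(
    Y: np.ndarray, patterns: list[MissingnessPattern], mean: np.ndarray, cov: np.ndarray
) -> float:
    ll = 0.0
    for pt in patterns:
        obs = list(pt.observed_set)
        if not obs:
            continue
        sub = Y[np.array(pt.row_indices)][:, obs]
        ll += stats.multivariate_normal.logpdf(
            sub, mean=mean[obs], cov=cov[np.ix_(obs, obs)], allow_singular=False
        ).sum()
    return float(ll)


def em_mean_cov(
    table: CohortTable | pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """ML mean and covariance of an incomplete table by EM.

    The observed-data log-likelihood is non-decreasing across iterations;
    convergence is declared when its successive change falls below ``tol``.
    Returns (mean, cov, log-likelihood trace).
    """
    values = table.values if isinstance(table, CohortTable) else table
    Y = np.asarray(values, dtype=float)
    n, p = Y.shape
    if n < 2:
        raise ValueError("need at least 2 records")
    obs_counts = (~np.isnan(Y)).sum(axis=0)
    if (obs_counts < 2).any():
        raise ValueError("every variable must be observed at least twice")

    mask = np.isnan(Y)
    patterns = extract_patterns(mask)

    # init: observed means, diagonal observed variances
    mean = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    var[var <= 0] = 1.0
    cov = np.diag(var)

    trace: list[float] = []
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pt in patterns:
            rows = np.array(pt.row_indices)
            obs = np.array(pt.observed_set, dtype=int)
            mis = np.setdiff1d(np.arange(p), obs)
            Yo = Y[rows][:, obs]
            if mis.size == 0:
                T1 += Yo.sum(axis=0)
                T2 += Yo.T @ Yo
                continue
            Soo = cov[np.ix_(obs, obs)]
            Smo = cov[np.ix_(mis, obs)]
            sol = np.linalg.solve(Soo, (Yo - mean[obs]).T)  # (|obs|, n_j)
            Ym = mean[mis][None, :] + (Smo @ sol).T
            cond = cov[np.ix_(mis, mis)] - Smo @ np.linalg.solve(Soo, Smo.T)
            X = np.empty((len(rows), p))
            X[:, obs] = Yo
            X[:, mis] = Ym
            T1 += X.sum(axis=0)
            T2 += X.T @ X
            T2[np.ix_(mis, mis)] += len(rows) * cond
        mean_new = T1 / n
        cov_new = T2 / n - np.outer(mean_new, mean_new)
        cov_new += ridge * np.eye(p)
        mean, cov = mean_new, cov_new
        ll = _observed_loglik(Y, patterns, mean, cov)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            return mean, cov, trace
    raise ConvergenceError(
        f"EM did not converge in {max_iter} iterations", mean, cov
    )


# ---------------------------------------------------------------------------
# Little's test


def littles_mcar_test(
    table: CohortTable | pd.DataFrame,
    alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> LittleTestResult:
    """Little's chi-square test of the MCAR hypothesis."""
    values = table.values if isinstance(table, CohortTable) else table
    Y = np.asarray(values, dtype=float)
    n, p = Y.shape
    patterns = extract_patterns(np.isnan(Y))
    if len(patterns) < 2:
        raise TestUndefinedError(
            "only one missingness pattern; Little's test is undefined (df = 0)"
        )
    mean, cov, _ = em_mean_cov(values, tol=tol, max_iter=max_iter)

    # every pattern contributes, whatever its size: the restricted
    # covariance is the *global* EM estimate, so pattern counts as small as
    # one record pose no singularity problem (rows with no observed cells
    # carry no information and are skipped)
    d2 = 0.0
    df = -p
    for pt in patterns:
        obs = list(pt.observed_set)
        if not obs:
            continue
        df += len(obs)
        sub = Y[np.array(pt.row_indices)][:, obs]
        diff = sub.mean(axis=0) - mean[obs]
        Soo = cov[np.ix_(obs, obs)]
        try:
            d2 += pt.count * float(diff @ np.linalg.solve(Soo, diff))
        except np.linalg.LinAlgError as err:
            raise SingularPatternError(
                f"singular restricted covariance for pattern {pt.observed_set}"
            ) from err
    if df <= 0:
        raise TestUndefinedError(f"non-positive degrees of freedom ({df})")
    p_value = float(stats.chi2.sf(d2, df))
    return LittleTestResult(
        d2=float(d2),
        df=int(df),
        p_value=p_value,
        n_patterns=len(patterns),
        em_mean=mean,
        em_cov=cov,
    )


def missingness_report(table: CohortTable) -> pd.DataFrame:
    """Per-column missing counts and percentages, descending."""
    miss = table.mask.sum(axis=0)
    out = pd.DataFrame(
        {
            "variable": miss.index,
            "n_missing": miss.to_numpy(),
            "pct_missing": 100.0 * miss.to_numpy() / table.n_records,
        }
    )
    return out.sort_values("pct_missing", ascending=False, ignore_index=True)
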