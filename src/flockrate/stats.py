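"""Cohort-level descriptive and associative statistics.

Indicator distributions from recall surveys are typically right-skewed
with occasional extreme values, so summaries centre on the median and
range; means and standard errors are reported alongside for
comparability with the wider literature.  Outliers are flagged with
Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) but never removed — every
respondent's recall is treated as equally trustworthy, and the median
is robust to them.  Associations use rank statistics throughout
(Spearman correlation, Kruskal–Wallis); p-values are reported raw,
with no multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantiles import DEFAULT_METHOD, quantile

__all__ = [
    "IndicatorSummary",
    "GroupCompareResult",
    "EmptySummaryError",
    "summarize",
    "summary_table",
    "rank_correlation_matrix",
    "group_compare",
    "percentage",
]


class EmptySummaryError(ValueError):
    """No defined values to summarize."""


@dataclass
class IndicatorSummary:
    variable: str
    n_defined: int
    median: float
    min: float
    max: float
    mean: float
    standard_error: Optional[float]
    lower_fence: Optional[float]
    upper_fence: Optional[float]
    n_outliers: Optional[int]


def summarize(
    values: Sequence[float], variable: str = "", method: str = DEFAULT_METHOD
) -> IndicatorSummary:
    """Median/range/mean/SE summary with Tukey outlier fences.

    Values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are counted as
    outliers but retained in every statistic.  Fences need at least 4
    defined values; the standard error needs at least 2.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise EmptySummaryError("no defined values to summarize")
    n = int(arr.size)
    se = float(np.std(arr, ddof=1) / math.sqrt(n)) if n >= 2 else None
    lower = upper = None
    n_outliers = None
    if n >= 4:
        q1 = quantile(arr, 0.25, method=method)
        q3 = quantile(arr, 0.75, method=method)
        iqr = q3 - q1
        lower = q1 - 1.5 * iqr
        upper = q3 + 1.5 * iqr
        n_outliers = int(np.sum((arr < lower) | (arr > upper)))
    return IndicatorSummary(
        variable=variable,
        n_defined=n,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        standard_error=se,
        lower_fence=lower,
        upper_fence=upper,
        n_outliers=n_outliers,
    )


def summary_table(frame: pd.DataFrame, method: str = DEFAULT_METHOD) -> pd.DataFrame:
    """Summarize every numeric column of an indicator table.

    Columns with no defined values are skipped.  Output mirrors the
    survey-report layout: median (min–max), mean (se), fences and
    outlier counts, one row per indicator.
    """
    rows = []
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            continue
        values = frame[col].to_numpy(dtype=float)
        if np.all(np.isnan(values)):
            continue
        s = summarize(values, variable=col, method=method)
        rows.append(
            {
                "variable": s.variable,
                "n": s.n_defined,
                "median": s.median,
                "min": s.min,
                "max": s.max,
                "mean": s.mean,
                "se": s.standard_error,
                "lower_fence": s.lower_fence,
                "upper_fence": s.upper_fence,
                "n_outliers": s.n_outliers,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def rank_correlation_matrix(
    table: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlation matrix with p-values.

    Returns (rho, p) as symmetric DataFrames with unit diagonal on rho.
    Pairs with fewer than ``min_n`` complete observations, or with a
    constant column, are NaN.
    """
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(cols)
    rho = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    for i, a in enumerate(cols):
        rho.iloc[i, i] = 1.0
        pval.iloc[i, i] = 0.0
        for j in range(i + 1, k):
            b = cols[j]
            pair = table[[a, b]].dropna()
            if len(pair) < min_n:
                continue
            x = pair[a].to_numpy(dtype=float)
            y = pair[b].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r, p = sps.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = float(r)
            pval.iloc[i, j] = pval.iloc[j, i] = float(p)
    return rho, pval


@dataclass
class GroupCompareResult:
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame  # n, median, q1, q3 per group


def group_compare(
    values: Sequence[float], groups: Sequence, method: str = DEFAULT_METHOD
) -> GroupCompareResult:
    """Kruskal–Wallis rank comparison of a variable across groups.

    Requires at least 2 groups of at least 2 defined values each.  The
    H statistic carries the standard tie correction; per-group medians
    and quartiles are reported alongside.
    """
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    frame = frame.dropna(subset=["value"])
    counts = frame.groupby("group").size()
    usable = counts[counts >= 2].index
    if len(usable) < 2:
        raise ValueError(
            "group comparison needs at least 2 groups with at least 2 defined values"
        )
    frame = frame[frame["group"].isin(usable)]
    samples = [g["value"].to_numpy() for _, g in frame.groupby("group")]
    pooled = frame["value"].to_numpy()
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*samples)
    summaries = frame.groupby("group")["value"].agg(
        n="size",
        median="median",
        q1=lambda v: quantile(v, 0.25, method=method),
        q3=lambda v: quantile(v, 0.75, method=method),
    )
    return GroupCompareResult(
        statistic=float(stat), p_value=float(p), group_summaries=summaries
    )


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Share of a cohort as a percentage, rounded for reporting."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return round(100.0 * numerator / denominator, decimals)
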