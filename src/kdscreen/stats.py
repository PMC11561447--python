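"""Group-comparison and association statistics: pooled two-sample t test
(from raw data or printed summaries), uncorrected 2x2 chi-square, and
Spearman rank correlation."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    pooled_sd: float


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Student's pooled-variance two-sample t test from group summaries.

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2),
    t = (mean1-mean2) / (sp sqrt(1/n1 + 1/n2)), df = n1+n2-2,
    two-tailed p from the t distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    sp = math.sqrt(sp2)
    diff = mean1 - mean2
    if sp == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0, pooled_sd=0.0)
        raise ValueError("zero variance with unequal means")
    t = diff / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=float(p), mean_diff=diff, pooled_sd=sp)


def pooled_t_from_raw(x1: Sequence[float], x2: Sequence[float]) -> TTestResult:
    """Pooled t test computed from the raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return pooled_t_from_summary(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ChiSquareResult:
    """Uncorrected Pearson chi-square for a 2x2 table [[a, b], [c, d]].

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1. No Yates
    continuity correction is applied.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate margin: a row or column total is zero")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    p = float(sps.chi2.sf(chi2, 1))
    return ChiSquareResult(chi2=float(chi2), df=1, p=p)


def spearman(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    r is the Pearson correlation of the midranks. ``method="t"`` (default)
    computes p from the t approximation t = r sqrt((n-2)/(1-r^2));
    ``method="permutation"`` enumerates all rank permutations (exact,
    n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: constant input vector")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    elif method == "permutation":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            rp = float(np.corrcoef(rx, perm)[0, 1])
            count += abs(rp) >= abs(r) - 1e-12
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpearmanResult(r=r, p=p, n=n)


DEFAULT_CORRELATION_VARIABLES = ["moca_k", "cbt_accuracy", "mean_ht_ms", "mean_ft_ms"]


def correlation_matrix(
    records: pd.DataFrame, variables: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations among the given columns.

    Returns (r_matrix, p_matrix) as symmetric DataFrames with a unit
    diagonal (p diagonal is NaN).
    """
    variables = list(variables) if variables is not None else DEFAULT_CORRELATION_VARIABLES
    k = len(variables)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(records[variables[i]], records[variables[j]])
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.p
    return (
        pd.DataFrame(r, index=variables, columns=variables),
        pd.DataFrame(p, index=variables, columns=variables),
    )


def group_comparison_table(
    records: pd.DataFrame,
    *,
    group_col: str = "group",
    groups: tuple[str, str] = ("HC", "MCI"),
    continuous: Sequence[str] | None = None,
    binary: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variable group comparison: pooled t for continuous variables,
    uncorrected chi-square for binary ones. One row per variable with the
    statistic, df, p value and group means/counts."""
    g1 = records[records[group_col] == groups[0]]
    g2 = records[records[group_col] == groups[1]]
    if continuous is None:
        continuous = [
            c
            for c in records.columns
            if c not in (group_col, "participant_id", "sex")
            and pd.api.types.is_numeric_dtype(records[c])
        ]
    binary = list(binary) if binary is not None else (["sex"] if "sex" in records else [])
    rows = []
    for col in continuous:
        res = pooled_t_from_raw(g1[col], g2[col])
        rows.append(
            {
                "variable": col,
                "test": "t",
                "statistic": res.t,
                "df": res.df,
                "p": res.p,
                "group1_mean": float(g1[col].mean()),
                "group1_sd": float(g1[col].std(ddof=1)),
                "group2_mean": float(g2[col].mean()),
                "group2_sd": float(g2[col].std(ddof=1)),
            }
        )
    for col in binary:
        levels = sorted(records[col].dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"binary variable {col!r} must have exactly 2 levels")
        a = int((g1[col] == levels[0]).sum())
        b = int((g2[col] == levels[0]).sum())
        c = int((g1[col] == levels[1]).sum())
        d = int((g2[col] == levels[1]).sum())
        res = chi_square_2x2(a, b, c, d)
        rows.append(
            {
                "variable": col,
                "test": "chi2",
                "statistic": res.chi2,
                "df": res.df,
                "p": res.p,
                "group1_mean": np.nan,
                "group1_sd": np.nan,
                "group2_mean": np.nan,
                "group2_sd": np.nan,
            }
        )
    return pd.DataFrame(rows)
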