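"""Descriptive and group-comparison statistics for the cohort table.

Chi-square on 2x2 tables (without Yates continuity correction by default —
the convention that reproduces printed cohort-table statistics from raw
counts), Mann-Whitney U reported as min(U_x, U_y) with mid-ranks, pooled or
Welch two-sample t, and Pearson/Spearman correlation. Thin, validated
wrappers around scipy.stats with a uniform result record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "ContingencyTable2x2",
    "GroupComparison",
    "chi_square_2x2",
    "mann_whitney_u",
    "two_sample_t",
    "correlation",
    "cohort_report",
]

#: below this product of sample sizes, the Mann-Whitney p is computed exactly
EXACT_U_LIMIT = 400


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d with rows = groups, columns = category levels."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(v < 0 or v != int(v) for v in counts):
            raise ParameterError("counts must be non-negative integers")
        if sum(counts) < 1:
            raise ParameterError("table total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    value: float
    df: float | None
    p_value: float
    group_summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError("p-value outside [0, 1]")


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> GroupComparison:
    """Pearson chi-square on a 2x2 table, df = 1, correction off by default."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateInputError("a table margin is zero")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=continuity_correction)
    return GroupComparison(
        statistic_name="chi2",
        value=float(chi2),
        df=float(dof),
        p_value=float(p),
        group_summaries={"counts": [[table.a, table.b], [table.c, table.d]]},
    )


def mann_whitney_u(x, y) -> GroupComparison:
    """Mann-Whitney U = min(U_x, U_y), mid-ranks for ties.

    The p-value uses exact enumeration when n_x * n_y <= 400 and the data
    are tie-free, otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= EXACT_U_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u_min = min(u_x, len(x) * len(y) - u_x)
    return GroupComparison(
        statistic_name="U",
        value=u_min,
        df=None,
        p_value=float(min(res.pvalue, 1.0)),
        group_summaries={
            "x": {"n": len(x), "median": float(np.median(x))},
            "y": {"n": len(y), "median": float(np.median(y))},
        },
    )


def two_sample_t(x, y, pooled: bool = True) -> GroupComparison:
    """Two-sample t test; pooled variance (df = n_x + n_y - 2) by default."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 2 or len(y) < 2:
        raise DegenerateInputError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) + np.var(y, ddof=1) < 1e-24:
        raise DegenerateInputError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    df = float(res.df)
    return GroupComparison(
        statistic_name="t",
        value=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        group_summaries={
            "x": {"n": len(x), "mean": float(x.mean()), "sd": float(x.std(ddof=1))},
            "y": {"n": len(y), "mean": float(y.mean()), "sd": float(y.std(ddof=1))},
        },
    )


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateInputError("need equal-length samples of >= 3")
    if np.ptp(x) < 1e-15 or np.ptp(y) < 1e-15:
        raise DegenerateInputError("constant input")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ParameterError(f"unknown correlation method {method!r}")


def cohort_report(
    table: pd.DataFrame,
    group_col: str,
    continuous: str = "mannwhitney",
) -> pd.DataFrame:
    """Group-comparison summary of a two-group cohort table.

    Numeric columns get mean (SD) per group plus a Mann-Whitney U (or pooled
    t with ``continuous='t'``); two-level non-numeric columns get counts and
    a chi-square. Returns one row per variable.
    """
    groups = table[group_col].unique()
    if len(groups) != 2:
        raise DegenerateInputError("group column must have exactly 2 levels")
    g0 = table[table[group_col] == groups[0]]
    g1 = table[table[group_col] == groups[1]]
    rows = []
    for col in table.columns:
        if col == group_col:
            continue
        if pd.api.types.is_numeric_dtype(table[col]):
            if continuous == "t":
                cmp = two_sample_t(g0[col], g1[col])
            else:
                cmp = mann_whitney_u(g0[col], g1[col])
            summary = [
                f"{g[col].mean():.1f} ({g[col].std(ddof=1):.1f})" for g in (g0, g1)
            ]
        else:
            levels = sorted(table[col].dropna().unique())
            if len(levels) != 2:
                continue
            counts = [
                [int((g[col] == lv).sum()) for lv in levels] for g in (g0, g1)
            ]
            cmp = chi_square_2x2(
                ContingencyTable2x2(
                    counts[0][0], counts[0][1], counts[1][0], counts[1][1]
                )
            )
            summary = [f"{c[0]}/{c[1]}" for c in counts]
        rows.append(
            {
                "variable": col,
                f"group_{groups[0]}": summary[0],
                f"group_{groups[1]}": summary[1],
                "statistic": cmp.statistic_name,
                "value": cmp.value,
                "df": cmp.df,
                "p": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)
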