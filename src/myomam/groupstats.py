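"""Group comparisons, regressions and aging summaries over morphometry records.

Mirrors the statistical treatment used for pooled-organelle TEM panels:
two-tailed two-sample t-tests for two groups, one-way ANOVA with
Bonferroni-adjusted pairwise t-tests for three or more, and simple linear
regression reporting the Pearson correlation constant r with its t-based
p-value.  Mitochondria are treated as independent observations (pooled
across animals); within-animal clustering is noted in output metadata as a
caveat, not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "compare_groups",
    "fit_simple_regression",
    "aging_summary",
]

OBSERVATION_UNIT_NOTE = (
    "observations are pooled organelles; within-animal clustering not modeled"
)


@dataclass
class GroupComparison:
    variable: str
    groups: list[str]
    test: str  # 't_test' or 'anova_bonferroni'
    statistic: float
    p_value: float
    pairwise_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    note: str = OBSERVATION_UNIT_NOTE


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def compare_groups(
    values: dict[str, list | np.ndarray],
    method: str | None = None,
    equal_var: bool = False,
    variable: str = "",
) -> GroupComparison:
    """Compare >=2 groups of measurements.

    Two groups use a two-tailed two-sample t-test (Welch by default;
    ``equal_var=True`` pools variances).  More than two groups use one-way
    ANOVA plus Bonferroni-adjusted pairwise t-tests.
    """
    names = list(values)
    arrays = {g: np.asarray(values[g], dtype=float) for g in names}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    if method is None:
        method = "t_test" if len(names) == 2 else "anova_bonferroni"
    if method == "t_test":
        if len(names) != 2:
            raise ValueError("t_test requires exactly two groups")
        res = stats.ttest_ind(arrays[names[0]], arrays[names[1]], equal_var=equal_var)
        return GroupComparison(variable, names, "t_test",
                               float(res.statistic), float(res.pvalue))
    if method == "anova_bonferroni":
        f, p = stats.f_oneway(*arrays.values())
        m = len(names) * (len(names) - 1) // 2
        pairwise = {}
        for g1, g2 in combinations(names, 2):
            t = stats.ttest_ind(arrays[g1], arrays[g2], equal_var=equal_var)
            pairwise[(g1, g2)] = min(1.0, m * float(t.pvalue))
        return GroupComparison(variable, names, "anova_bonferroni",
                               float(f), float(p), pairwise)
    raise ValueError(f"unknown method {method!r}")


def fit_simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x; r is the Pearson correlation and p
    comes from the t distribution on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression is degenerate")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def aging_summary(
    records: pd.DataFrame,
    group_col: str = "age_group",
    young_label: str = "young",
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group means/SDs and percent change versus the young group.

    Percent change is 100*(mean_group - mean_young)/mean_young per variable;
    a zero young mean yields NaN (flagged, not an error).
    """
    if young_label not in set(records[group_col]):
        raise ValueError(f"young group {young_label!r} absent")
    if variables is None:
        variables = [
            c
            for c in records.columns
            if c != group_col and pd.api.types.is_numeric_dtype(records[c])
        ]
    rows = []
    grouped = records.groupby(group_col, observed=True)
    young_means = grouped.get_group(young_label)[variables].mean()
    for gname, sub in grouped:
        for var in variables:
            mean = sub[var].mean()
            y = young_means[var]
            change = 100.0 * (mean - y) / y if y != 0 else np.nan
            rows.append(
                {
                    "variable": var,
                    "group": gname,
                    "mean": mean,
                    "sd": sub[var].std(ddof=1),
                    "n": int(sub[var].notna().sum()),
                    "pct_change_vs_young": change,
                    "undefined_change": bool(y == 0),
                }
            )
    return pd.DataFrame(rows)
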