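"""Two-group and multi-group comparisons of per-sample indicators.

Thin wrappers over scipy for the two tests the analysis uses everywhere:
Welch's unequal-variance t-test (two-sided, Welch–Satterthwaite degrees of
freedom) and one-way ANOVA.  Both accept plain numeric vectors so any
per-sample indicator (DIN, median coverage, duplicate percent, variant-count
difference, ...) can be compared between FF/FFPE or across extraction kits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupTestResult:
    test: str            # welch_t | one_way_anova
    statistic: float
    df: tuple[float, ...]  # (df,) for t; (k-1, N-k) for ANOVA
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def welch_t(a: Sequence[float], b: Sequence[float]) -> GroupTestResult:
    """Welch's two-sample t-test (unequal variances, two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        # identical constants: no evidence of difference
        return GroupTestResult("welch_t", 0.0, (float(len(a) + len(b) - 2),), 1.0)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return GroupTestResult("welch_t", float(res.statistic), (float(df),), float(res.pvalue))


def one_way_anova(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """One-way fixed-effects ANOVA; df = (k-1, N-k)."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    df = (float(k - 1), float(n_total - k))
    if all(g.var(ddof=1) == 0 for g in arrays) and len({g[0] for g in arrays}) == 1:
        warnings.warn("all groups are the same constant; reporting F=0", RuntimeWarning)
        return GroupTestResult("one_way_anova", 0.0, df, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*arrays)
    return GroupTestResult("one_way_anova", float(res.statistic), df, float(res.pvalue))


def compare_indicator_groups(
    df: pd.DataFrame, value_col: str, group_col: str, test: str = "auto"
) -> GroupTestResult:
    """Run the appropriate comparison on a per-sample indicator table.

    ``test='auto'`` picks Welch's t for 2 groups and one-way ANOVA otherwise.
    """
    groups = [g[value_col].to_numpy(float) for _, g in df.groupby(group_col)]
    if test == "auto":
        test = "welch_t" if len(groups) == 2 else "one_way_anova"
    if test == "welch_t":
        if len(groups) != 2:
            raise ValueError(f"welch_t needs exactly 2 groups, found {len(groups)}")
        return welch_t(groups[0], groups[1])
    if test == "one_way_anova":
        return one_way_anova(groups)
    raise ValueError(f"unknown test {test!r}")


def result_table(results: dict[str, GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(indicator=name, test=r.test, statistic=r.statistic,
                 df=",".join(f"{d:g}" for d in r.df), p_value=r.p_value)
            for name, r in results.items()
        ]
    )
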