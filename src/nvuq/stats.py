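"""Group statistics: per-mouse averaging and the normality-gated test.

All comparisons run on one value per mouse (averages within animals are the
statistically independent unit).  Each group is checked for normality with
the Shapiro-Wilk test at alpha = 0.05; if both groups pass, groups are
compared with the classical equal-variance two-sample t-test, otherwise with
the two-sided Mann-Whitney U test (exact when the combined sample is small
and tie-free).  Summaries follow the test: mean +/- SEM for t, median with
25th/75th percentiles for U.  No multiple-testing correction and no outlier
removal are applied; the number of tests run is annotated on reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .io import AnnotationTable

__all__ = ["ComparisonResult", "RegressionResult", "per_mouse_average",
           "compare_groups", "age_regression"]


@dataclass
class ComparisonResult:
    measure: str
    test_used: str                      # "student_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]]
    n_per_group: dict[str, int]
    normality_p: dict[str, float]
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class RegressionResult:
    measure: str
    slope_per_month: float
    intercept: float
    slope_p: float
    group_slopes: dict[str, float] = field(default_factory=dict)
    slope_difference_p: float | None = None


def per_mouse_average(raw: pd.DataFrame) -> AnnotationTable:
    """Collapse raw rows to one arithmetic mean per mouse per measure.

    ``raw`` needs columns mouse_id, group, measure, value (age_months
    optional).  Unequal numbers of raw observations per mouse are fine —
    each mouse contributes exactly one row downstream.
    """
    if "age_months" not in raw.columns:
        raw = raw.assign(age_months=np.nan)
    out = (raw.groupby(["mouse_id", "group", "measure"], as_index=False)
              .agg(value=("value", "mean"), age_months=("age_months", "mean")))
    return AnnotationTable("cohort", out)


def _values(table: AnnotationTable | pd.DataFrame, measure: str):
    df = table.df if isinstance(table, AnnotationTable) else table
    df = df[df["measure"] == measure]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    return groups, [df.loc[df["group"] == g, "value"].to_numpy(float)
                    for g in groups]


def compare_groups(table: AnnotationTable | pd.DataFrame, measure: str,
                   alpha: float = 0.05, *, gate: str = "per_group",
                   equal_var: bool = True) -> ComparisonResult:
    """Normality-gated two-group comparison on per-mouse values.

    Shapiro-Wilk per group at ``alpha``; both pass -> two-sided equal-variance
    t-test (Welch behind ``equal_var=False``); otherwise two-sided
    Mann-Whitney U, exact for combined n <= 20 without ties, normal
    approximation with tie correction otherwise.
    """
    groups, (a, b) = _values(table, measure)
    if min(len(a), len(b)) < 2:
        raise ValueError("need >= 2 mice per group")
    if min(len(a), len(b)) < 3:
        raise ValueError("need >= 3 mice per group for the normality gate")
    sw = {g: float(sps.shapiro(v).pvalue) for g, v in zip(groups, (a, b))}
    if gate == "pooled":
        normal = sps.shapiro(np.concatenate([a - a.mean(), b - b.mean()])).pvalue > alpha
    else:
        normal = all(p > alpha for p in sw.values())

    if normal:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        test, stat, p = "student_t", float(res.statistic), float(res.pvalue)
        summaries = {g: {"mean": float(v.mean()),
                         "sem": float(v.std(ddof=1) / np.sqrt(len(v)))}
                     for g, v in zip(groups, (a, b))}
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test, stat, p = "mann_whitney_u", float(res.statistic), float(res.pvalue)
        summaries = {g: {"median": float(np.median(v)),
                         "q25": float(np.percentile(v, 25)),
                         "q75": float(np.percentile(v, 75))}
                     for g, v in zip(groups, (a, b))}
    return ComparisonResult(measure, test, stat, p, summaries,
                            {g: len(v) for g, v in zip(groups, (a, b))}, sw, alpha)


def age_regression(table: AnnotationTable | pd.DataFrame, measure: str
                   ) -> RegressionResult:
    """OLS of the per-mouse measure on age, with a group-slope-difference test.

    Fits ``value ~ age_months`` pooled for the headline slope and
    ``value ~ age_months * group`` for per-group slopes; the interaction
    term's two-sided p-value tests whether the slopes differ.
    """
    df = (table.df if isinstance(table, AnnotationTable) else table)
    df = df[df["measure"] == measure].dropna(subset=["age_months"]).copy()
    if df["age_months"].nunique() < 3:
        raise ValueError("age regression needs >= 3 distinct ages")
    pooled = smf.ols("value ~ age_months", data=df).fit()
    result = RegressionResult(measure,
                              float(pooled.params["age_months"]),
                              float(pooled.params["Intercept"]),
                              float(pooled.pvalues["age_months"]))
    if df["group"].nunique() == 2 and \
            df.groupby("group")["age_months"].nunique().min() >= 2:
        inter = smf.ols("value ~ age_months * C(group)", data=df).fit()
        base = float(inter.params["age_months"])
        groups = sorted(df["group"].unique())
        iname = [n for n in inter.params.index if n.startswith("age_months:")][0]
        result.group_slopes = {groups[0]: base,
                               groups[1]: base + float(inter.params[iname])}
        result.slope_difference_p = float(inter.pvalues[iname])
    return result
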