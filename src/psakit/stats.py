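"""Descriptive and inferential statistics for the cohort analyses.

Continuous variables are compared with the classic pooled-variance Student
t-test (two groups) or one-way ANOVA (an omnibus F across the four
race/ethnicity groups); categorical variables with the Pearson chi-square
test without continuity correction.  Correlations between tumor volume and
each PSA derivative use Pearson's r, optionally as a partial correlation
with age removed; linear associations use ordinary least squares, either
univariable or age-adjusted.  p <= 0.05 is flagged significant; no
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

SUMMARY_VARIABLES = [
    ("age", "Age, years"),
    ("psa_ng_ml", "PSA, ng/mL"),
    ("psad", "PSA density, ng/mL/gm"),
    ("psam", "PSA mass, ug"),
    ("psamd", "PSA mass density, ug/gm"),
    ("prostate_weight_g", "Prostate weight, gm"),
    ("tumor_volume", "Tumor volume, cm3"),
]


@dataclass
class StatResult:
    estimate: Optional[float]
    statistic: float
    p_value: float
    n: int
    df: float
    method: str

    @property
    def significant(self) -> bool:
        """The study's significance rule: p <= 0.05."""
        return self.p_value <= 0.05


@dataclass
class GroupSummary:
    """Per-group descriptive row (mean / median / min / max per variable,
    counts and percentages per categorical level)."""

    group: str
    n: int
    continuous: pd.DataFrame  # index: variable; columns mean, median, min, max, n
    categorical: dict[str, pd.DataFrame]  # variable -> (count, percent) per level


def t_test(x, y) -> StatResult:
    """Two-sided pooled-variance (Student) t-test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) != np.mean(y):
        raise ValueError("both samples have zero variance; t statistic undefined")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return StatResult(
        estimate=float(np.mean(x) - np.mean(y)),
        statistic=float(t),
        p_value=float(p),
        n=len(x) + len(y),
        df=len(x) + len(y) - 2,
        method="student_t_pooled",
    )


def anova_f(*samples) -> StatResult:
    """One-way ANOVA across >= 2 groups (omnibus test for group differences)."""
    if len(samples) < 2:
        raise ValueError("anova_f needs at least two groups")
    samples = [np.asarray(s, float) for s in samples]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*samples)
    n = sum(len(s) for s in samples)
    return StatResult(
        estimate=None,
        statistic=float(f),
        p_value=float(p),
        n=n,
        df=len(samples) - 1,
        method="oneway_anova",
    )


def chi_square(table) -> StatResult:
    """Pearson chi-square on an r x c count table, (r-1)(c-1) df, no
    continuity correction."""
    table = np.asarray(table, float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column must have a positive sum")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatResult(
        estimate=None,
        statistic=float(chi2),
        p_value=float(p),
        n=int(table.sum()),
        df=float(dof),
        method="pearson_chi_square",
    )


def pearson_r(x, y) -> StatResult:
    """Pearson correlation with the t-based two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must be paired with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return StatResult(
        estimate=float(r),
        statistic=float(r * np.sqrt((len(x) - 2) / max(1e-300, 1 - r**2))),
        p_value=float(p),
        n=len(x),
        df=len(x) - 2,
        method="pearson",
    )


def partial_corr(x, y, z) -> StatResult:
    """First-order partial correlation of x and y with covariate z removed:

        r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

    Equivalent to the Pearson correlation of the residuals of x and y after
    each is regressed on z.  The p-value is t-based with n - 3 df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise ValueError("x, y, z must be paired with n >= 4")
    r_xy = sps.pearsonr(x, y)[0]
    r_xz = sps.pearsonr(x, z)[0]
    r_yz = sps.pearsonr(y, z)[0]
    denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
    if denom_sq <= 1e-14:
        raise ValueError("a variable is collinear with the covariate; partial correlation undefined")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)
    n = len(x)
    df = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = 2 * sps.t.sf(abs(t), df)
    return StatResult(estimate=r, statistic=float(t), p_value=float(p), n=n, df=df, method="partial_pearson")


def linear_model(response, predictor, age=None):
    """OLS of the response (tumor volume) on one PSA derivative, optionally
    age-adjusted.  Returns the fitted statsmodels results object; slopes are
    in ``.params`` and t-based p-values in ``.pvalues``."""
    y = np.asarray(response, float)
    columns = {"predictor": np.asarray(predictor, float)}
    if age is not None:
        columns["age"] = np.asarray(age, float)
    X = sm.add_constant(pd.DataFrame(columns))
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} observations")
    return sm.OLS(y, X).fit()


def summarize_groups(
    df: pd.DataFrame,
    grouping: str = "race_ethnicity",
    variables: Sequence[tuple[str, str]] | None = None,
    categoricals: Sequence[str] = ("bmi_category", "institution"),
) -> list[GroupSummary]:
    """Per-group descriptive summaries shaped like the cohort tables.

    Percentages for categoricals are computed within the group's non-missing
    denominator for that variable.  Unknown race/ethnicity is analyzed inside
    the OTHER group.
    """
    if variables is None:
        variables = [(c, label) for c, label in SUMMARY_VARIABLES if c in df.columns]
    df = df.copy()
    if grouping == "race_ethnicity":
        df[grouping] = df[grouping].replace({"UNKNOWN": "OTHER"})
    out: list[GroupSummary] = []
    for group, sub in df.groupby(grouping, sort=False):
        cont = pd.DataFrame(
            {
                "mean": {label: sub[c].mean() for c, label in variables},
                "median": {label: sub[c].median() for c, label in variables},
                "min": {label: sub[c].min() for c, label in variables},
                "max": {label: sub[c].max() for c, label in variables},
                "n": {label: int(sub[c].notna().sum()) for c, label in variables},
            }
        )
        cats = {}
        for cat in categoricals:
            if cat not in sub.columns or cat == grouping:
                continue
            counts = sub[cat].value_counts(dropna=True)
            denom = int(counts.sum())
            cats[cat] = pd.DataFrame(
                {"count": counts, "percent": 100.0 * counts / denom if denom else np.nan}
            )
        out.append(GroupSummary(group=str(group), n=len(sub), continuous=cont, categorical=cats))
    return out


def group_comparison_pvalues(
    df: pd.DataFrame,
    grouping: str = "race_ethnicity",
    variables: Sequence[tuple[str, str]] | None = None,
    categoricals: Sequence[str] = ("bmi_category", "institution"),
) -> pd.DataFrame:
    """Omnibus p-value per variable across groups: one-way ANOVA (or pooled t
    for exactly two groups) for continuous variables, chi-square for
    categoricals."""
    if variables is None:
        variables = [(c, label) for c, label in SUMMARY_VARIABLES if c in df.columns]
    df = df.copy()
    if grouping == "race_ethnicity":
        df[grouping] = df[grouping].replace({"UNKNOWN": "OTHER"})
    groups = [sub for _, sub in df.groupby(grouping, sort=False)]
    rows = []
    for column, label in variables:
        samples = [g[column].dropna().to_numpy(float) for g in groups]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            continue
        res = t_test(samples[0], samples[1]) if len(samples) == 2 else anova_f(*samples)
        rows.append({"variable": label, "kind": "continuous", "p_value": res.p_value, "method": res.method})
    for cat in categoricals:
        if cat not in df.columns or cat == grouping:
            continue
        table = pd.crosstab(df[grouping], df[cat])
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        res = chi_square(table.to_numpy())
        rows.append({"variable": cat, "kind": "categorical", "p_value": res.p_value, "method": res.method})
    return pd.DataFrame(rows)


def association_report(
    df: pd.DataFrame,
    metrics: Sequence[str] = ("psa_ng_ml", "psad", "psam", "psamd"),
    by_group: bool = True,
) -> pd.DataFrame:
    """Correlation and regression of tumor volume on each derivative.

    For the whole cohort and (optionally) per race/ethnicity group: Pearson
    r, age-partialled r, the univariable OLS slope, and the age-adjusted
    slope, each with its p-value.
    """
    frames = [("All", df)]
    if by_group:
        frames += [(str(g), sub) for g, sub in df.groupby("race_ethnicity", sort=False)]
    rows = []
    for name, sub in frames:
        for metric in metrics:
            cols = sub[[metric, "tumor_volume", "age"]].dropna()
            if len(cols) < 4:
                continue
            x = cols[metric].to_numpy(float)
            tv = cols["tumor_volume"].to_numpy(float)
            age = cols["age"].to_numpy(float)
            pear = pearson_r(x, tv)
            part = partial_corr(x, tv, age)
            uni = linear_model(tv, x)
            multi = linear_model(tv, x, age=age)
            rows.append(
                {
                    "group": name,
                    "metric": metric,
                    "n": len(cols),
                    "pearson_r": pear.estimate,
                    "pearson_p": pear.p_value,
                    "partial_r_age_removed": part.estimate,
                    "partial_p": part.p_value,
                    "uni_slope": float(uni.params["predictor"]),
                    "uni_p": float(uni.pvalues["predictor"]),
                    "multi_slope_age_adj": float(multi.params["predictor"]),
                    "multi_p": float(multi.pvalues["predictor"]),
                }
            )
    return pd.DataFrame(rows)
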