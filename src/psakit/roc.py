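"""ROC curves, optimal-cutoff selection, and screening classification.

Screening convention used throughout: a score **at or above** the cutoff is a
positive call (a man whose PSAD equals the printed cutoff screens positive).
Cutoff selection is the *upper-left* criterion: the operating point closest
in Euclidean distance to the ideal corner (false-positive rate 0,
sensitivity 1); Youden's J (sensitivity + specificity - 1) is available as
an alternative.  Thresholds are evaluated at observed score values, never at
midpoints, so results are exactly reproducible on discrete data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .derivatives import SIGNIFICANT_TV_CM3

#: Printed precision per metric for cutoff reporting.
CUTOFF_DECIMALS = {"psa": 2, "psad": 2, "psam": 2, "psamd": 3}

#: Metric name -> cohort-frame column holding its score.
METRIC_COLUMNS = {"psa": "psa_ng_ml", "psad": "psad", "psam": "psam", "psamd": "psamd"}


class SingleClassError(ValueError):
    """ROC analysis needs at least one positive and one negative."""


@dataclass
class RocCurve:
    """Operating points of a score for a binary outcome.

    One point per distinct observed score value (positive call = score >=
    threshold) plus the degenerate all-negative point at threshold +inf.
    ``thresholds`` ascend; sensitivity is non-increasing and specificity
    non-decreasing along them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = _trapezoid_auc(self.sensitivity, self.specificity)

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _trapezoid_auc(sensitivity: np.ndarray, specificity: np.ndarray) -> float:
    fpr = 1.0 - np.asarray(specificity, float)
    tpr = np.asarray(sensitivity, float)
    # sort by FPR then TPR so vertical segments are traversed bottom-up
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def build_roc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve of ``scores`` for boolean ``labels`` (True = diseased).

    Raises :class:`SingleClassError` when only one class is present.  Tied
    scores share an operating point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if np.any(np.isnan(scores)):
        raise ValueError("scores must not contain NaN")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise SingleClassError(f"labels contain no {missing} example")
    thresholds = np.append(np.unique(scores), np.inf)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    # P(score >= t) via searchsorted on the sorted class scores; computed as
    # count ratios so operating points are bit-identical to direct counting
    sens = (n_pos - np.searchsorted(pos, thresholds, side="left")) / n_pos
    spec = np.searchsorted(neg, thresholds, side="left") / n_neg
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the curve; equals the concordance statistic
    (fraction of positive/negative pairs ranked correctly, ties half)."""
    return roc.auc


def optimal_cutoff_upper_left(roc: RocCurve, criterion: str = "upper_left") -> tuple[float, float, float]:
    """Cutoff whose operating point is closest to the (FPR 0, sensitivity 1)
    corner, as ``(threshold, sensitivity, specificity)``.

    Ties break toward higher specificity, then toward the higher threshold.
    ``criterion="youden"`` maximizes sensitivity + specificity - 1 instead.
    """
    sens = roc.sensitivity
    spec = roc.specificity
    if criterion == "upper_left":
        objective = (1.0 - spec) ** 2 + (1.0 - sens) ** 2  # minimize
    elif criterion == "youden":
        objective = -(sens + spec - 1.0)
    else:
        raise ValueError(f"unknown criterion {criterion!r}; use 'upper_left' or 'youden'")
    # lexicographic: objective asc, specificity desc, threshold desc
    order = np.lexsort((-roc.thresholds, -spec, objective))
    best = order[0]
    return float(roc.thresholds[best]), float(sens[best]), float(spec[best])


@dataclass
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def confusion_at_cutoff(scores, labels, cutoff: float) -> Confusion:
    """2x2 counts and rates at a cutoff (positive call = score >= cutoff).

    Rates with a zero denominator are reported as ``None``, never as 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    called = scores >= cutoff
    tp = int(np.sum(called & labels))
    fp = int(np.sum(called & ~labels))
    tn = int(np.sum(~called & ~labels))
    fn = int(np.sum(~called & labels))

    def _rate(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return Confusion(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def sensitivity_at_fixed_specificity(roc: RocCurve, spec_target: float = 0.80) -> float:
    """Sensitivity at the smallest achievable specificity >= ``spec_target``.

    The conservative attainment rule: among operating points whose
    specificity meets the target, take the one with the least specificity
    (the most sensitive end of the attaining set); points tied on that
    specificity contribute their best sensitivity.  The all-negative point
    guarantees the target is always attainable (sensitivity 0 in the worst
    case).
    """
    attain = roc.specificity >= spec_target
    min_spec = roc.specificity[attain].min()
    at = attain & (roc.specificity == min_spec)
    return float(roc.sensitivity[at].max())


def compare_sensitivity_bootstrap(
    scores_a,
    scores_b,
    labels,
    spec_target: float = 0.80,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Paired percentile bootstrap for the difference in sensitivity at fixed
    specificity between two scores measured on the same records.

    Records are resampled with replacement; each resample rebuilds both ROC
    curves and recomputes the sensitivities at ``spec_target``.  Returns the
    observed difference ``sens_a - sens_b``, a two-sided percentile p-value
    for a zero difference, and the 95% percentile interval.  Resamples that
    lose one of the outcome classes are redrawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores_a, scores_b and labels must be paired (equal length)")

    def _delta(idx) -> float:
        sens_a = sensitivity_at_fixed_specificity(build_roc(scores_a[idx], labels[idx]), spec_target)
        sens_b = sensitivity_at_fixed_specificity(build_roc(scores_b[idx], labels[idx]), spec_target)
        return sens_a - sens_b

    n = len(labels)
    observed = _delta(np.arange(n))
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if labels[idx].any() and not labels[idx].all():
                break
        deltas[b] = _delta(idx)
    p_low = float(np.mean(deltas <= 0.0))
    p_high = float(np.mean(deltas >= 0.0))
    p_value = min(1.0, 2.0 * min(p_low, p_high))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return {
        "delta": observed,
        "p_value": p_value,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
    }


@dataclass
class CutoffReport:
    """One per-group, per-metric row: the selected cutoff with its resulting
    operating characteristics (percent scale)."""

    group: str
    metric: str
    cutoff: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    auc: Optional[float]
    n: int
    n_pos: int
    estimable: bool = True


def table3_report(
    df: pd.DataFrame,
    groups: Sequence[str] | None = None,
    metrics: Sequence[str] = ("psa", "psad", "psam", "psamd"),
    group_column: str = "race_ethnicity",
    criterion: str = "upper_left",
) -> list[CutoffReport]:
    """Optimal cutoffs per group x metric with resulting sensitivity,
    specificity, PPV, NPV, and AUC (all percent scale).

    ``df`` must carry derivative columns (see ``add_derivatives``) and the
    boolean ``significant`` outcome.  Groups with a single outcome class are
    flagged not estimable rather than dropped.
    """
    if groups is None:
        groups = list(pd.unique(df[group_column]))
    reports: list[CutoffReport] = []
    for group in groups:
        sub = df[df[group_column] == group]
        sub = sub[sub["significant"].notna()]
        labels = sub["significant"].to_numpy(dtype=bool)
        for metric in metrics:
            column = METRIC_COLUMNS.get(metric, metric)
            scores_all = sub[column]
            ok = scores_all.notna().to_numpy()
            scores = scores_all.to_numpy(dtype=float)[ok]
            lab = labels[ok]
            try:
                roc = build_roc(scores, lab)
            except SingleClassError:
                reports.append(
                    CutoffReport(
                        group=str(group), metric=metric, cutoff=None, sensitivity=None,
                        specificity=None, ppv=None, npv=None, auc=None,
                        n=len(lab), n_pos=int(lab.sum()), estimable=False,
                    )
                )
                continue
            cutoff, _, _ = optimal_cutoff_upper_left(roc, criterion=criterion)
            conf = confusion_at_cutoff(scores, lab, cutoff)
            pct = lambda x: None if x is None else 100.0 * x
            reports.append(
                CutoffReport(
                    group=str(group),
                    metric=metric,
                    cutoff=cutoff,
                    sensitivity=pct(conf.sensitivity),
                    specificity=pct(conf.specificity),
                    ppv=pct(conf.ppv),
                    npv=pct(conf.npv),
                    auc=100.0 * roc.auc,
                    n=len(lab),
                    n_pos=int(lab.sum()),
                )
            )
    return reports


@dataclass
class ScreeningClassification:
    """Per-record TP/FP/TN/FN screening labels plus stratified counts."""

    labels: pd.Series
    counts: dict[str, int]
    by_bmi_category: pd.DataFrame
    by_pw_side: pd.DataFrame
    median_pw: float


def screening_classification(
    df: pd.DataFrame,
    metric: str,
    cutoff: float,
    tv_threshold: float = SIGNIFICANT_TV_CM3,
) -> ScreeningClassification:
    """Classify each record against a screening cutoff.

    A record at or above the cutoff with tumor volume >= the threshold is a
    true positive; above the cutoff with smaller volume, a false positive;
    and symmetrically for TN/FN below the cutoff.  Counts are stratified by
    BMI category and by prostate weight relative to the in-sample median
    (records at the median count as the "small" side).
    """
    column = METRIC_COLUMNS.get(metric, metric)
    sub = df[df["significant"].notna() & df[column].notna()]
    scores = sub[column].to_numpy(dtype=float)
    diseased = sub["tumor_volume"].to_numpy(dtype=float) >= tv_threshold
    called = scores >= cutoff
    label = np.where(called, np.where(diseased, "TP", "FP"), np.where(diseased, "FN", "TN"))
    labels = pd.Series(label, index=sub.index, name="screen_class")
    counts = {k: int(np.sum(label == k)) for k in ("TP", "FP", "TN", "FN")}
    median_pw = float(sub["prostate_weight_g"].median())
    pw_side = np.where(sub["prostate_weight_g"].to_numpy(float) > median_pw, "above_median_pw", "at_or_below_median_pw")
    by_pw = pd.crosstab(pd.Series(pw_side, index=sub.index, name="pw_side"), labels)
    by_bmi = pd.crosstab(sub["bmi_category"], labels, dropna=False)
    return ScreeningClassification(
        labels=labels,
        counts=counts,
        by_bmi_category=by_bmi,
        by_pw_side=by_pw,
        median_pw=median_pw,
    )


def reports_to_frame(reports: Sequence[CutoffReport], round_output: bool = False) -> pd.DataFrame:
    """CutoffReport list as a DataFrame; optionally rounded to printed
    precision (cutoff per metric via :data:`CUTOFF_DECIMALS`, rates 1 dp)."""
    rows = []
    for r in reports:
        row = {
            "group": r.group,
            "metric": r.metric,
            "cutoff": r.cutoff,
            "sensitivity_pct": r.sensitivity,
            "specificity_pct": r.specificity,
            "ppv_pct": r.ppv,
            "npv_pct": r.npv,
            "auc_pct": r.auc,
            "n": r.n,
            "n_pos": r.n_pos,
            "estimable": r.estimable,
        }
        if round_output and r.estimable:
            row["cutoff"] = round(r.cutoff, CUTOFF_DECIMALS.get(r.metric, 3))
            for key in ("sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct", "auc_pct"):
                if row[key] is not None:
                    row[key] = round(row[key], 1)
        rows.append(row)
    return pd.DataFrame(rows)
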