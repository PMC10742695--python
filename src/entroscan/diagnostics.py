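"""Diagnostic statistics for ROI-mean entropy values.

Covers the statistics layer of an entropy-imaging study: Pearson correlation
of ROI-mean entropy with log10 of a continuous severity (e.g. hepatic fat
fraction), ROC analysis per grade split (≥mild, ≥moderate, ≥severe) with a
DeLong 95% CI on the AUC, the Youden-optimal cutoff, and the classification
metrics derived from the confusion matrix at that cutoff (sensitivity,
specificity, LR+, LR−, PPV, NPV).  Predictive values are computed from the
study's own confusion matrix, i.e. at the cohort prevalence, not
population-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve, auc as _auc

from .errors import DegenerateSplitError, EntroscanError

__all__ = [
    "ROCResult",
    "pearson_log10",
    "roc_analysis",
    "delong_ci",
    "dynamic_range_compare",
    "SPLITS",
]

#: Binary splits of the 4-grade scheme: positives are grades >= threshold.
SPLITS = {"ge1": 1, "ge2": 2, "ge3": 3}


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve plus Youden-cutoff metrics for one grade split."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci95: tuple[float, float]
    cutoff: float
    youden: float
    metrics_at_cutoff: dict[str, float]


def pearson_log10(entropy, severity) -> tuple[float, float]:
    """Pearson r (and two-sided p) between entropy and log10(severity)."""
    e = np.asarray(entropy, dtype=np.float64)
    s = np.asarray(severity, dtype=np.float64)
    if e.size != s.size:
        raise EntroscanError("entropy and severity lengths differ")
    if e.size < 3:
        raise EntroscanError("need at least 3 subjects")
    if np.any(s <= 0):
        raise EntroscanError("severities must be > 0 for the log10 transform")
    if np.std(e) == 0 or np.std(s) == 0:
        raise EntroscanError("zero variance in correlation input")
    r, p = stats.pearsonr(np.log10(s), e)
    return float(r), float(p)


def delong_ci(
    scores, labels, alpha: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong 95% CI for binary labels (higher score => positive).

    Uses the midrank formulation of the DeLong covariance; the CI is the
    normal-approximation interval clipped to [0, 1].
    """
    y = np.asarray(labels, dtype=bool)
    x = np.asarray(scores, dtype=np.float64)
    pos, neg = x[y], x[~y]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise DegenerateSplitError("degenerate split")
    allx = np.concatenate([pos, neg])
    ranks = stats.rankdata(allx)  # midranks
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    auc_val = (np.sum(ranks[:m]) - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks[:m] - rank_pos) / n  # placement values of positives
    v01 = 1.0 - (ranks[m:] - rank_neg) / m  # placements of negatives
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    lo = max(0.0, auc_val - z * se)
    hi = min(1.0, auc_val + z * se)
    return float(auc_val), (float(lo), float(hi))


def _confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    with np.errstate(divide="ignore"):
        lr_pos = sens / (1.0 - spec) if spec < 1.0 else np.inf
        lr_neg = (1.0 - sens) / spec if spec > 0.0 else np.inf
    ppv = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    npv = tn / (tn + fn) if (tn + fn) > 0 else np.nan
    return {
        "youden": sens + spec - 1.0,
        "sensitivity": sens,
        "specificity": spec,
        "lr_pos": float(lr_pos),
        "lr_neg": float(lr_neg),
        "ppv": ppv,
        "npv": npv,
        "tp": float(tp), "fn": float(fn), "tn": float(tn), "fp": float(fp),
    }


def roc_analysis(scores, grades, split: str = "ge1") -> ROCResult:
    """ROC analysis of entropy scores for one ordinal-grade split.

    Positives are grades >= the split threshold; higher entropy is read as
    more severe (scores are used as-is, no auto-orientation).  The operating
    cutoff maximizes Youden's index, ties broken toward higher sensitivity;
    all reported metrics are recomputed from the confusion matrix at that
    cutoff (prediction rule: score >= cutoff).
    """
    if split not in SPLITS:
        raise EntroscanError(f"split must be one of {sorted(SPLITS)}")
    g = np.asarray(grades)
    x = np.asarray(scores, dtype=np.float64)
    y = g >= SPLITS[split]
    if y.all() or not y.any():
        raise DegenerateSplitError("degenerate split")
    fpr, tpr, thr = roc_curve(y, x, drop_intermediate=False)
    auc_val, ci = delong_ci(x, y)
    # consistency: trapezoid AUC over the empirical curve equals the
    # rank-based DeLong point estimate up to fp rounding
    assert abs(_auc(fpr, tpr) - auc_val) < 1e-9
    j = tpr - fpr
    best = np.flatnonzero(j == np.max(j))
    pick = best[np.argmax(tpr[best])]  # ties -> higher sensitivity
    cutoff = float(thr[pick])
    pred = x >= cutoff
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    metrics = _confusion_metrics(tp, fn, tn, fp)
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc_val,
        auc_ci95=ci,
        cutoff=cutoff,
        youden=metrics["youden"],
        metrics_at_cutoff=metrics,
    )


def dynamic_range_compare(dr_hist, dr_kde) -> tuple[float, dict]:
    """Paired t-test of per-subject dynamic ranges (KDE vs histogram).

    Returns the two-sided p-value and a box-plot-ready summary (median and
    quartiles per estimator).  A constant nonzero paired difference makes the
    t statistic degenerate; by convention p -> 0 is reported with a warning.
    """
    a = np.asarray(dr_hist, dtype=np.float64)
    b = np.asarray(dr_kde, dtype=np.float64)
    if a.size != b.size:
        raise EntroscanError("paired dynamic-range lists must have equal length")
    diff = b - a
    if np.std(diff, ddof=1) == 0.0:
        if np.all(diff == 0.0):
            p = 1.0
        else:
            warnings.warn("zero-variance nonzero paired difference; reporting p=0")
            p = 0.0
    else:
        p = float(stats.ttest_rel(b, a).pvalue)
    summary = {}
    for name, vals in (("hist", a), ("kde", b)):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summary[name] = {
            "median": float(med), "q1": float(q1), "q3": float(q3),
            "mean": float(np.mean(vals)),
        }
    return p, summary
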