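"""ROC curves, tie-corrected AUC, and DeLong's paired AUC comparison.

The AUC is the Mann-Whitney probability estimate with midrank handling of
ties — exact ties between a case and a control count one half.  Midranks
matter here because linear predictors dominated by binary covariates tie
exactly.  DeLong's method tests the difference of two correlated AUCs
computed on the same patients, using per-subject placement values to
estimate the covariance of the paired AUCs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats
from sklearn import metrics as _skmetrics


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling:
    (#concordant + 0.5 * #tied) / (n1 * n0)."""
    scores, labels = _validate(np.asarray(scores), np.asarray(labels))
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)  # midranks
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclasses.dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    tpr: np.ndarray  # sensitivity
    auc: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve with one point per distinct threshold plus the (0,0) and
    (1,1) endpoints; its trapezoidal area equals :func:`auc` exactly."""
    scores, labels = _validate(np.asarray(scores), np.asarray(labels))
    fpr, tpr, thr = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
    )


@dataclasses.dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-subject placement values with midrank tie correction.

    For case i, V10_i is the fraction of controls its score beats (ties
    half); for control j, V01_j the fraction of cases beating it.  The AUC
    is the mean of either vector.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01, float(v10.mean())


def delong_paired_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test for the difference of two paired AUCs.

    Both score vectors must refer to the same subjects in the same order.
    The variance of the AUC difference combines the placement-value
    covariances across cases and controls; z is referred to the standard
    normal, two-sided.  A degenerate pairing — zero variance with unequal
    AUCs — raises; zero variance with equal AUCs yields p = 1.
    """
    scores_a, labels = _validate(np.asarray(scores_a), np.asarray(labels))
    scores_b, _ = _validate(np.asarray(scores_b), np.asarray(labels))

    va10, va01, auc_a = _placements(scores_a, labels)
    vb10, vb01, auc_b = _placements(scores_b, labels)
    m, n = len(va10), len(va01)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 cases and 2 controls")

    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    var_diff = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    var_diff = max(var_diff, 0.0)
    d = auc_a - auc_b
    if var_diff == 0.0:
        if d == 0.0:
            return DeLongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("degenerate pairing: zero variance with unequal AUCs")
    z = d / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_diff=var_diff, z=float(z), p=float(p))
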