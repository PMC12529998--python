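"""Statistical tests and ROC machinery used by the evaluation reports.

Three tests back the analyses: the two-sample Kolmogorov–Smirnov test for
differences between class-wise property distributions, DeLong's test for the
difference of two correlated AUCs computed on the same cases, and the pooled
two-proportion z-test for community co-membership fractions. ROC curves are
built one-vs-rest per class; the trapezoidal AUC equals the tie-corrected
Mann–Whitney estimate (ties counted 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportions_ztest

from .errors import DataError

__all__ = [
    "TestResult",
    "ROCResult",
    "ks_two_sample",
    "roc_curve",
    "delong_test",
    "delong_auc",
    "two_proportion_test",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int


@dataclass(frozen=True)
class ROCResult:
    """ROC points (FPR, TPR), trapezoidal AUC, and the class treated as positive."""

    points: np.ndarray
    auc: float
    positive_label: object

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def ks_two_sample(x, y) -> TestResult:
    """Two-sample KS test, D = sup |ECDF_x - ECDF_y|.

    The p-value comes from the asymptotic Kolmogorov distribution with the
    usual effective-sample-size correction n1*n2/(n1+n2); exact small-sample
    p-values are deliberately not computed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("KS test requires non-empty samples")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "ks_two_sample",
                      x.size, y.size)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise DataError(f"need exactly two label values, got {uniq.tolist()}")
    return uniq


def roc_curve(scores, labels, positive_label=None) -> ROCResult:
    """One-vs-rest ROC by sweeping thresholds over the unique scores.

    ``positive_label`` defaults to the larger of the two label values. The AUC
    is the trapezoidal integral of the curve, identical to the Mann–Whitney
    U statistic divided by n_pos * n_neg with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise DataError("scores and labels must have equal length")
    uniq = _check_binary(labels)
    if positive_label is None:
        positive_label = uniq[-1]
    fpr, tpr, _ = _sk_roc_curve(labels, scores, pos_label=positive_label)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(points=points, auc=auc, positive_label=positive_label)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_variance(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their covariance matrix via DeLong's structural components.

    ``scores`` has one row per classifier; ``y`` is boolean (True = positive).
    """
    pos = scores[:, y]
    neg = scores[:, ~y]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01)
    s10 = np.cov(v10)
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def delong_test(scores1, scores2, labels, positive_label=None) -> TestResult:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score vectors must refer to the same cases with the same labels. The
    statistic is z = (AUC1 - AUC2) / sqrt(var(AUC1 - AUC2)) with the variance
    from the structural-components estimator; p is two-sided normal. Identical
    classifiers (zero variance of the difference) give z = 0, p = 1.
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise DataError("paired DeLong test needs equal-length scores and labels")
    uniq = _check_binary(labels)
    if positive_label is None:
        positive_label = uniq[-1]
    y = labels == positive_label
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    aucs, cov = _delong_auc_variance(np.vstack([s1, s2]), y)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if np.isclose(diff, 0.0):
        z, p = 0.0, 1.0
    elif var <= 0:
        z, p = float(np.sign(diff) * np.inf), 0.0
    else:
        z = float(diff / np.sqrt(var))
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(z, min(p, 1.0), "delong", n_pos, n_neg)


def delong_auc(scores, labels, positive_label=None) -> tuple[float, float]:
    """(AUC, variance) of a single classifier from the same estimator."""
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = _check_binary(labels)
    if positive_label is None:
        positive_label = uniq[-1]
    y = labels == positive_label
    aucs, cov = _delong_auc_variance(s[None, :], y)
    return float(aucs[0]), float(cov[0, 0])


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test, two-sided normal p-value."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise DataError("two_proportion_test requires n >= 1")
        if not 0 <= k <= n:
            raise DataError(f"count {k} outside [0, {n}]")
    if k1 * n2 == k2 * n1:  # identical proportions, incl. degenerate pooled 0/1
        return TestResult(0.0, 1.0, "two_proportion", n1, n2)
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return TestResult(float(z), float(p), "two_proportion", n1, n2)
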