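"""Evaluation statistics: ROC machinery, threshold calibration, confusion
metrics, Wilson intervals, and the exact binomial test.

The positive class is TRUTH (label 1) throughout; a prediction is positive
iff its score is >= the operating threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from ..records import ConfigurationError


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    source: str  # "validation_windows" | "pooled_oof_sessions"
    j_value: float


@dataclass
class SessionScore:
    subject_id: str
    session_id: str
    label: int
    score: float
    n_windows: int


def aggregate_session_scores(
    window_probs: np.ndarray,
    session_ids: np.ndarray,
    subject_ids: np.ndarray,
    labels: np.ndarray,
) -> list[SessionScore]:
    """Arithmetic mean of window probabilities per session (insertion order)."""
    out: dict[str, SessionScore] = {}
    for p, sess, subj, y in zip(window_probs, session_ids, subject_ids, labels):
        if sess not in out:
            out[sess] = SessionScore(str(subj), str(sess), int(y), 0.0, 0)
        rec = out[sess]
        rec.score += float(p)
        rec.n_windows += 1
    for rec in out.values():
        rec.score /= rec.n_windows
    return list(out.values())


def _check_two_class(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("both classes must be present")


def roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float, float]]:
    """ROC curve as (FPR, TPR, threshold), thresholds = descending unique
    scores preceded by a +inf sentinel; positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_class(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    points = []
    for t in thresholds:
        pred = scores >= t
        tpr = float((pred & (labels == 1)).sum()) / n_pos
        fpr = float((pred & (labels == 0)).sum()) / n_neg
        points.append((fpr, tpr, float(t)))
    return points


def youden_threshold(scores: np.ndarray, labels: np.ndarray,
                     source: str = "validation_windows") -> OperatingPoint:
    """argmax over ROC thresholds of J = TPR - FPR, ties toward the smallest
    (finite) threshold."""
    points = roc_points(scores, labels)
    best_j, best_t = -np.inf, np.inf
    for fpr, tpr, t in points:
        j = tpr - fpr
        if j > best_j or (j == best_j and t < best_t):
            best_j, best_t = j, t
    if not np.isfinite(best_t):  # degenerate single-score case
        best_t = float(np.max(scores))
    return OperatingPoint(threshold=float(best_t), source=source, j_value=float(best_j))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted one half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_class(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[len(neg):].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_class(labels)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order] == 1
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    # keep the last point at each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    precision, recall = precision[distinct], recall[distinct]
    prev_recall, area = 0.0, 0.0
    for p, r in zip(precision, recall):
        area += p * (r - prev_recall)
        prev_recall = r
    return float(area)


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """95% (default) Wilson score interval, returned in percent."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ConfigurationError("require 0 <= k <= n")
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (100.0 * (center - half), 100.0 * (center + half))


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value (minimum-likelihood method)."""
    if not 0 <= k <= n:
        raise ConfigurationError("require 0 <= k <= n")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


@dataclass
class MetricsReport:
    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    balanced_accuracy: float
    precision_lie: float
    recall_lie: float
    f1_lie: float
    precision_truth: float
    recall_truth: float
    f1_truth: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    mcc: float
    roc_auc: float | None = None
    pr_auc: float | None = None
    wilson_accuracy: tuple[float, float] | None = None
    wilson_recall_lie: tuple[float, float] | None = None
    wilson_recall_truth: tuple[float, float] | None = None
    degenerate: bool = False  # a zero-denominator rate was guarded to 0

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def classification_report(
    predictions: np.ndarray,
    labels: np.ndarray,
    scores: np.ndarray | None = None,
    with_wilson: bool = False,
) -> MetricsReport:
    """All confusion-derived metrics; TRUTH (1) is the positive class."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    tp = int(((predictions == 1) & (labels == 1)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())
    return report_from_counts(tn, fp, fn, tp, scores=scores, labels=labels, with_wilson=with_wilson)


def report_from_counts(
    tn: int, fp: int, fn: int, tp: int,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    with_wilson: bool = False,
) -> MetricsReport:
    n = tn + fp + fn + tp
    degenerate = False

    accuracy, d = _safe_div(tp + tn, n); degenerate |= d
    recall_truth, d = _safe_div(tp, tp + fn); degenerate |= d
    recall_lie, d = _safe_div(tn, tn + fp); degenerate |= d
    precision_truth, d = _safe_div(tp, tp + fp); degenerate |= d
    precision_lie, d = _safe_div(tn, tn + fn); degenerate |= d
    f1_truth, d = _safe_div(2 * precision_truth * recall_truth, precision_truth + recall_truth); degenerate |= d
    f1_lie, d = _safe_div(2 * precision_lie * recall_lie, precision_lie + recall_lie); degenerate |= d

    support_lie, support_truth = tn + fp, tp + fn
    macro_precision = (precision_lie + precision_truth) / 2
    macro_recall = (recall_lie + recall_truth) / 2
    macro_f1 = (f1_lie + f1_truth) / 2
    wp, d = _safe_div(support_lie * precision_lie + support_truth * precision_truth, n); degenerate |= d
    wr, d = _safe_div(support_lie * recall_lie + support_truth * recall_truth, n); degenerate |= d
    wf, d = _safe_div(support_lie * f1_lie + support_truth * f1_truth, n); degenerate |= d

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = float((tp * tn - fp * fn) / mcc_den) if mcc_den > 0 else 0.0
    if mcc_den == 0:
        degenerate = True

    report = MetricsReport(
        tn=tn, fp=fp, fn=fn, tp=tp,
        accuracy=accuracy,
        balanced_accuracy=(recall_lie + recall_truth) / 2,
        precision_lie=precision_lie, recall_lie=recall_lie, f1_lie=f1_lie,
        precision_truth=precision_truth, recall_truth=recall_truth, f1_truth=f1_truth,
        macro_precision=macro_precision, macro_recall=macro_recall, macro_f1=macro_f1,
        weighted_precision=wp, weighted_recall=wr, weighted_f1=wf,
        mcc=mcc, degenerate=degenerate,
    )
    if scores is not None and labels is not None and len(np.unique(labels)) == 2:
        report.roc_auc = roc_auc(scores, labels)
        report.pr_auc = pr_auc(scores, labels)
    if with_wilson and n > 0:
        report.wilson_accuracy = wilson_interval(tp + tn, n)
        if tn + fp > 0:
            report.wilson_recall_lie = wilson_interval(tn, tn + fp)
        if tp + fn > 0:
            report.wilson_recall_truth = wilson_interval(tp, tp + fn)
    return report
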