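"""Classification metrics and method-agreement statistics.

Two layers live here.  The first is the per-class metric arithmetic used
to grade a frame classifier: one-vs-rest confusion counts, sensitivity /
specificity / precision / accuracy / F1, sample-weighted averages, and
threshold-swept ROC (trapezoidal AUC) and precision–recall (trapezoidal
AP) curves.  The second compares two timing series — e.g. effective
withdrawal times measured by the system and by an endoscopist — with the
standard method-comparison toolkit: the single-measure absolute-agreement
two-way random-effects intraclass correlation ICC(A,1) with its F-based
confidence interval, Bland–Altman bias and 95% limits of agreement,
Pearson correlation, and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "CurvePoints",
    "AgreementReport",
    "confusion_counts",
    "class_metrics",
    "weighted_average",
    "roc_auc",
    "pr_ap",
    "agreement",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    """Scalar metrics for one class, as fractions in [0, 1].

    ``flags`` records any zero-denominator conventions applied (the
    affected metric is reported as 0 rather than undefined).
    """

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    flags: Tuple[str, ...] = ()

    def as_percent(self, ndigits: int = 2) -> Dict[str, float]:
        return {
            name: round(100 * getattr(self, name), ndigits)
            for name in ("sensitivity", "specificity", "precision", "accuracy", "f1")
        }


@dataclass(frozen=True)
class CurvePoints:
    """An ROC or PR curve: ordered (x, y) points plus the trapezoidal area."""

    x: Tuple[float, ...]
    y: Tuple[float, ...]
    area: float


@dataclass
class AgreementReport:
    """Agreement between two paired timing series (seconds).

    Differences are taken as ``a - b`` (first series minus second), so a
    negative bias means the first method underestimates the second.
    """

    n: int
    icc: float
    icc_ci95: Tuple[float, float]
    pearson_r: float
    pearson_p: float
    bias: float
    loa_low: float
    loa_high: float
    wilcoxon_w: float
    wilcoxon_p: float
    flags: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# confusion counts / scalar metrics

def confusion_counts(
    truth: Sequence[str], predicted: Sequence[str], positive: str
) -> ConfusionCounts:
    """One-vs-rest counts for class ``positive`` from paired label lists."""
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    tp = sum(t == positive and p == positive for t, p in zip(truth, predicted))
    tn = sum(t != positive and p != positive for t, p in zip(truth, predicted))
    fp = sum(t != positive and p == positive for t, p in zip(truth, predicted))
    fn = sum(t == positive and p != positive for t, p in zip(truth, predicted))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(f"{name}_undefined")
        return 0.0
    return num / den


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 when both are 0."""
    if precision + sensitivity == 0:
        return 0.0
    return 2 * precision * sensitivity / (precision + sensitivity)


def class_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """Sensitivity, specificity, precision, accuracy and F1 from counts.

    Zero-denominator metrics are reported as 0 and flagged rather than
    raising, so weighted averages over classes stay defined.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    flags: List[str] = []
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", flags)
    spec = _ratio(counts.tn, counts.tn + counts.fp, "specificity", flags)
    prec = _ratio(counts.tp, counts.tp + counts.fp, "precision", flags)
    acc = (counts.tp + counts.tn) / counts.total
    return ClassMetrics(sens, spec, prec, acc, f1_score(prec, sens), tuple(flags))


def weighted_average(
    values: Sequence[float], weights: Sequence[float]
) -> float:
    """Dot product of ``values`` with ``weights`` normalized to sum 1.

    Typically the weights are per-class sample counts, so classes with
    more samples dominate the average.
    """
    if len(values) != len(weights):
        raise ValueError("values and weights lengths differ")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return float(np.asarray(values, dtype=float) @ (w / w.sum()))


# ---------------------------------------------------------------------------
# threshold-swept curves

def _curve_counts(
    scores: Sequence[float], truth: Sequence[int]
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Cumulative TP/FP over descending score thresholds, ties grouped."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth lengths differ")
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    sorted_scores = scores[order]
    # last index of each tie group
    boundaries = np.flatnonzero(np.diff(sorted_scores)) if len(scores) > 1 else np.array([], int)
    idx = np.append(boundaries, len(scores) - 1)
    tps = np.cumsum(sorted_truth)[idx]
    fps = np.cumsum(~sorted_truth)[idx]
    return tps, fps, int(truth.sum()), int((~truth).sum())


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> CurvePoints:
    """ROC curve by descending-score thresholding, area by trapezoids.

    Requires at least one positive and one negative instance.  Ties are
    grouped at a single threshold, which makes the all-equal-scores case
    collapse to the chance diagonal (AUC 0.5).
    """
    tps, fps, n_pos, n_neg = _curve_counts(scores, truth)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both a positive and a negative instance")
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    area = 0.5 * float(np.sum((fpr[1:] - fpr[:-1]) * (tpr[1:] + tpr[:-1])))
    return CurvePoints(tuple(fpr), tuple(tpr), area)


def pr_ap(scores: Sequence[float], truth: Sequence[int]) -> CurvePoints:
    """Precision–recall curve with average precision by trapezoidal
    integration of precision over recall.

    Requires at least one positive instance.  With an all-positive truth
    vector precision is identically 1, so AP is 1 regardless of scores.
    """
    tps, fps, n_pos, _ = _curve_counts(scores, truth)
    if n_pos == 0:
        raise ValueError("PR requires at least one positive instance")
    recall = tps / n_pos
    precision = tps / (tps + fps)
    # anchor the curve at recall 0 with the first threshold's precision
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    area = 0.5 * float(
        np.sum((recall[1:] - recall[:-1]) * (precision[1:] + precision[:-1]))
    )
    return CurvePoints(tuple(recall), tuple(precision), area)


# ---------------------------------------------------------------------------
# agreement between two timing series

def _icc_a1(data: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    """ICC(A,1): single-measure, absolute-agreement, two-way random model.

    ``data`` is (n subjects) x (k raters).  Returns the point estimate and
    its 95% confidence interval from the F-distribution bounds.
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0, (1.0, 1.0)
    icc = (msr - mse) / denom

    if mse == 0:
        return icc, (icc, icc)
    # confidence interval (single-measure absolute agreement)
    alpha = 0.05
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return icc, (icc, icc)
    fstar = msr / mse
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return icc, (float(lower), float(upper))


def _wilcoxon_signed_rank(diffs: np.ndarray) -> Tuple[float, float, List[str]]:
    """Wilcoxon signed-rank W and p: exact null for n <= 25, normal
    approximation with continuity correction above; zero differences are
    dropped per the Wilcoxon convention."""
    flags: List[str] = []
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        flags.append("wilcoxon_all_zero")
        return 0.0, 1.0, flags
    mode = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(mode == "approx"), mode=mode
    )
    return float(res.statistic), float(res.pvalue), flags


def agreement(series_a: Sequence[float], series_b: Sequence[float]) -> AgreementReport:
    """Full agreement report between two paired timing series.

    Computes ICC(A,1) with its 95% CI, Bland–Altman bias and limits of
    agreement (``a - b`` differences, bias ± 1.96 SD), Pearson r, and the
    Wilcoxon signed-rank test.  Degenerate inputs (zero-variance series,
    all-zero differences) are flagged and the affected statistics set to
    their conventional values rather than raising.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("agreement requires n >= 3 pairs")
    flags: List[str] = []

    icc, ci = _icc_a1(np.column_stack([a, b]))

    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd

    if a.std() == 0 or b.std() == 0:
        flags.append("pearson_zero_variance")
        r, rp = float("nan"), float("nan")
    else:
        r, rp = stats.pearsonr(a, b)

    w, wp, wflags = _wilcoxon_signed_rank(diffs)
    flags.extend(wflags)

    return AgreementReport(
        n=n,
        icc=float(icc),
        icc_ci95=(float(ci[0]), float(ci[1])),
        pearson_r=float(r),
        pearson_p=float(rp),
        bias=bias,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        wilcoxon_w=w,
        wilcoxon_p=wp,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# multiclass evaluation report

def evaluate_predictions(
    truth: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str] | None = None,
    confidences: Sequence[float] | None = None,
) -> Dict:
    """Per-class metrics plus sample-weighted averages, mirroring the
    per-class + weighted layout used for classifier test reports.

    When per-frame confidences are given, one-vs-rest AUC and AP are also
    computed per class using the confidence as the score for the
    predicted class (and zero otherwise); classes missing a positive or
    negative instance report null for the affected curve metric.
    """
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    report: Dict = {"classes": {}, "weighted": {}}
    weights = [sum(t == c for t in truth) for c in classes]
    per_class: Dict[str, Dict[str, float]] = {}
    for c in classes:
        cm = class_metrics(confusion_counts(truth, predicted, c))
        entry: Dict = {
            "counts": vars(confusion_counts(truth, predicted, c)),
            **{k: v for k, v in cm.as_percent().items()},
            "flags": list(cm.flags),
        }
        if confidences is not None:
            scores = [
                conf if p == c else 1.0 - conf
                for p, conf in zip(predicted, confidences)
            ]
            binary = [int(t == c) for t in truth]
            try:
                entry["auc"] = round(roc_auc(scores, binary).area, 4)
            except ValueError:
                entry["auc"] = None
            try:
                entry["ap_percent"] = round(100 * pr_ap(scores, binary).area, 2)
            except ValueError:
                entry["ap_percent"] = None
        per_class[c] = entry
        report["classes"][c] = entry
    for metric in ("sensitivity", "specificity", "precision", "accuracy", "f1"):
        report["weighted"][metric] = round(
            weighted_average([per_class[c][metric] for c in classes], weights), 2
        )
    report["n_samples"] = len(truth)
    return report
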