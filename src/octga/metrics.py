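"""Evaluation statistics for GA detection and segmentation.

Covers confusion-derived metrics at two levels (per-pixel segmentation and
per-scan/volume binary detection), agreement between predicted and
ground-truth GA areas (Pearson R and a two-way absolute-agreement
single-measure ICC with its F-based confidence interval), and pooled
pixel-wise ROC curves from model confidence maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AgreementReport",
    "ROCCurve",
    "pixel_confusion",
    "summary_metrics",
    "detection_eval",
    "dice",
    "pearson",
    "icc_agreement",
    "roc",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Confusion-derived summary; metrics with a zero denominator are NaN
    and the reason is recorded in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    counts: ConfusionCounts
    undefined: dict[str, str] = field(default_factory=dict)


@dataclass
class AgreementReport:
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_type: str = "ICC2"


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_bool(a) -> np.ndarray:
    v = np.asarray(a)
    if v.dtype != bool:
        uniq = np.unique(v)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("expected a binary array")
        v = v.astype(bool)
    return v


def pixel_confusion(pred, truth) -> ConfusionCounts:
    """Element-wise confusion counts between two binary arrays."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def summary_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity (recall), specificity, precision and F-score.

    F is the harmonic mean of precision and recall, defined as 0 when there
    are no true positives but positives exist somewhere (tp=0, fp+fn>0);
    components whose denominator is zero are NaN with a recorded reason.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    undefined: dict[str, str] = {}

    def ratio(num, den, name, reason):
        if den == 0:
            undefined[name] = reason
            return math.nan
        return num / den

    acc = (tp + tn) / counts.total
    sens = ratio(tp, tp + fn, "sensitivity", "no positive ground truth")
    spec = ratio(tn, tn + fp, "specificity", "no negative ground truth")
    prec = ratio(tp, tp + fp, "precision", "no positive predictions")
    if tp > 0:
        f = 2 * prec * sens / (prec + sens)
    elif fp + fn > 0:
        f = 0.0
    else:
        undefined["f_score"] = "no positives in prediction or truth"
        f = math.nan
    return MetricsReport(acc, sens, spec, prec, f, counts, undefined)


def dice(pred, truth) -> float:
    """Dice/F overlap of two binary arrays; 1.0 when both are empty."""
    c = pixel_confusion(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def detection_eval(pairs) -> tuple[ConfusionCounts, MetricsReport]:
    """Binary GA-presence evaluation over (predicted, true) presence pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty list of presence pairs")
    pred = np.array([bool(p) for p, _ in pairs])
    truth = np.array([bool(t) for _, t in pairs])
    counts = pixel_confusion(pred, truth)
    return counts, summary_metrics(counts)


def pearson(areas_pred, areas_truth) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t transform, n-2 df)."""
    x = np.asarray(areas_pred, dtype=float)
    y = np.asarray(areas_truth, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _two_way_mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of the two-way (targets x raters) ANOVA with k=2 raters."""
    data = np.stack([x, y], axis=1)  # (n targets, 2 raters)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse


def icc_agreement(
    areas_pred, areas_truth, confidence: float = 0.95, variant: str = "ICC2"
) -> AgreementReport:
    """Agreement between two area measurements of the same scans.

    The ICC is computed from the two-way ANOVA mean squares; the default
    ``variant`` "ICC2" is the two-way random-effects, absolute-agreement,
    single-measure form, with the F-distribution (Satterthwaite) confidence
    interval; "ICC3" gives the consistency form.  Pearson r/p are included
    for convenience.  Identical vectors give ICC = 1 with a degenerate
    interval.
    """
    x = np.asarray(areas_pred, dtype=float)
    y = np.asarray(areas_truth, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs for a meaningful ICC")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("degenerate variance: all measurements identical")
    r, p = pearson(x, y)
    if np.array_equal(x, y):
        return AgreementReport(r, p, 1.0, 1.0, 1.0, icc_type=variant)

    k = 2
    alpha = 1.0 - confidence
    msr, msc, mse = _two_way_mean_squares(x, y)
    if variant == "ICC3":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        ci_low = (f_l - 1) / (f_l + k - 1)
        ci_high = (f_u - 1) / (f_u + k - 1)
    elif variant == "ICC2":
        icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
        a = (k * icc) / (n * (1 - icc))
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    return AgreementReport(r, p, float(icc), float(ci_low), float(ci_high), icc_type=variant)


def roc(confidence_maps, truth_maps, pooling: str = "pixels") -> ROCCurve:
    """Pixel-pooled ROC over a set of confidence/truth map pairs.

    All pixels of all scans are pooled into one threshold sweep ("pixels");
    the curve includes the (0,0) and (1,1) endpoints and AUC is the
    trapezoid-rule area.
    """
    if pooling != "pixels":
        raise ValueError("only pixel pooling is implemented")
    if not isinstance(confidence_maps, (list, tuple)):
        confidence_maps, truth_maps = [confidence_maps], [truth_maps]
    confs, truths = [], []
    for c, t in zip(confidence_maps, truth_maps, strict=True):
        c = np.asarray(getattr(c, "values", c), dtype=float)
        t = _as_bool(getattr(t, "values", t))
        if c.shape != t.shape:
            raise ValueError("confidence/truth shape mismatch")
        if c.min() < 0 or c.max() > 1:
            raise ValueError("confidences must lie in [0, 1]")
        confs.append(c.ravel())
        truths.append(t.ravel())
    y = np.concatenate(truths)
    s = np.concatenate(confs)
    if y.all() or not y.any():
        raise ValueError("truth contains a single class; ROC undefined")

    from sklearn import metrics as skm

    fpr, tpr, thr = skm.roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(skm.auc(fpr, tpr)))


def plot_roc(curve: ROCCurve, path=None, label: str = "model"):
    """Render an ROC curve against the chance diagonal; save if ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, label=f"{label} (AUC = {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", color="orange", label="chance")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
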