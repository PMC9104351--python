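"""Confusion matrices, accuracy/precision/sensitivity reports, ten-fold CV
aggregation, and the SNR robustness sweep.

Metric conventions
------------------
For each class treated one-vs-rest, precision ``Pr = TP/(TP+FP) * 100`` and
sensitivity ``Se = TP/(TP+FN) * 100``; overall accuracy is the fraction of
correctly labeled beats.  Macro averages are the unweighted mean of the two
*unrounded* per-class values; all reported numbers are then rounded to two
decimals.  A class that receives no predictions has undefined precision and
is reported as NaN, never 0.

Cross-validation results are aggregated by summing the per-fold confusion
matrices, so the aggregate total equals the full dataset size, and the SNR
sweep re-runs the raw-record preprocessing pipeline at each noise level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import NoiseSpec, preprocess, stack_segments
from .records import LABELS


@dataclass
class ConfusionMatrix:
    """2x2 counts indexed (true class, predicted class), class order
    (normal, chf)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) treating ``cls`` as positive."""
        tp = int(self.counts[cls, cls])
        fp = int(self.counts[1 - cls, cls])
        fn = int(self.counts[cls, 1 - cls])
        tn = int(self.counts[1 - cls, 1 - cls])
        return tp, fp, tn, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    """Percent metrics rounded to two decimals; NaN marks an undefined value."""

    accuracy: float
    precision: dict[str, float]
    sensitivity: dict[str, float]
    macro_precision: float
    macro_sensitivity: float
    total: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": dict(self.precision),
            "sensitivity": dict(self.sensitivity),
            "macro_precision": self.macro_precision,
            "macro_sensitivity": self.macro_sensitivity,
            "total": self.total,
        }


def predict_labels(model, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
    """Argmax class per beat; a 50/50 tie resolves to the lower class index."""
    X = np.asarray(X, dtype=np.float64)
    out = np.empty(len(X), dtype=np.int64)
    for start in range(0, len(X), batch_size):
        logits = model.forward(X[start:start + batch_size], training=False)
        out[start:start + batch_size] = logits.argmax(axis=1)
    return out


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count (true, predicted) pairs; labels may be ints or label strings."""
    t = _as_int_labels(true_labels)
    p = _as_int_labels(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"label length mismatch: {len(t)} vs {len(p)}")
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def _as_int_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.array([LABELS.index(str(v)) for v in arr], dtype=np.int64)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/sensitivity and macro averages from a
    confusion matrix, as percentages rounded to two decimals."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * np.trace(cm.counts) / cm.total
    precision, sensitivity = {}, {}
    pr_raw, se_raw = [], []
    for cls, name in enumerate(LABELS):
        tp, fp, tn, fn = cm.one_vs_rest(cls)
        pr = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else math.nan
        se = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else math.nan
        precision[name] = round(pr, 2) if not math.isnan(pr) else math.nan
        sensitivity[name] = round(se, 2) if not math.isnan(se) else math.nan
        pr_raw.append(pr)
        se_raw.append(se)
    # macro averages over the unrounded per-class values
    macro_pr = round(float(np.mean(pr_raw)), 2) if not any(
        math.isnan(v) for v in pr_raw) else math.nan
    macro_se = round(float(np.mean(se_raw)), 2) if not any(
        math.isnan(v) for v in se_raw) else math.nan
    return MetricsReport(accuracy=round(acc, 2), precision=precision,
                         sensitivity=sensitivity, macro_precision=macro_pr,
                         macro_sensitivity=macro_se, total=cm.total)


def evaluate(model, segments) -> tuple[ConfusionMatrix, MetricsReport]:
    """Predict every beat and report the confusion matrix + metrics."""
    X, y, _ = stack_segments(segments)
    preds = predict_labels(model, X)
    cm = confusion_matrix(y, preds)
    return cm, metrics_from_confusion(cm)


def run_intra_cv(model_builder, segments, folds,
                 train_cfg) -> tuple[ConfusionMatrix, MetricsReport]:
    """Ten-fold-style cross-validation: train a fresh model per fold, sum
    the per-fold confusion matrices, and compute metrics on the aggregate
    (so the aggregate total equals the dataset size)."""
    from .training import train

    agg = ConfusionMatrix(np.zeros((2, 2), dtype=np.int64))
    for k, (train_segs, test_segs) in enumerate(folds):
        model = model_builder(k)
        X, y, _ = stack_segments(train_segs)
        train(model, X, y, train_cfg)
        cm, _ = evaluate(model, test_segs)
        agg = agg + cm
    return agg, metrics_from_confusion(agg)


def noise_robustness_sweep(model, raw_test_records,
                           snr_list=(math.inf, 24.0, 18.0, 12.0, 6.0),
                           seed: int = 0, target_fs: int = 250):
    """Evaluate a trained model on the raw test records at each SNR.

    Noise is injected into the raw traces *before* resampling/segmentation/
    normalization, one seeded realization per SNR row.  Returns an ordered
    dict ``snr -> (ConfusionMatrix, MetricsReport)``.
    """
    results: dict[float, tuple[ConfusionMatrix, MetricsReport]] = {}
    for snr in snr_list:
        noise = None if math.isinf(snr) else NoiseSpec(snr_db=float(snr),
                                                       rng_seed=seed)
        segments = preprocess(raw_test_records, noise=noise,
                              target_fs=target_fs)
        results[float(snr)] = evaluate(model, segments)
    return results


def render_report(cm: ConfusionMatrix, report: MetricsReport,
                  title: str = "") -> str:
    """Plain-text table in the confusion-matrix layout of the study tables."""
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'Original/Predicted':<20}{'Normal':>10}{'CHF':>10}"
                 f"{'Pr (%)':>10}{'Se (%)':>10}")
    for cls, name in enumerate(("Normal", "CHF")):
        key = LABELS[cls]
        lines.append(f"{name:<20}{cm.counts[cls, 0]:>10}{cm.counts[cls, 1]:>10}"
                     f"{report.precision[key]:>10}{report.sensitivity[key]:>10}")
    lines.append(f"{'Average (%)':<40}{report.macro_precision:>10}"
                 f"{report.macro_sensitivity:>10}")
    lines.append(f"{'Acc (%)':<40}{report.accuracy:>10}")
    return "\n".join(lines)
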