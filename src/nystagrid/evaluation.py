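"""One-vs-rest multi-class evaluation suite.

Metrics follow the one-vs-rest convention: each class in turn is treated
as positive and all others as negative, giving per-class TP/FP/FN/TN from
the confusion matrix.  Per-class metrics are

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    FPR         = 1 - specificity
    F-beta      = (1 + b^2) P S / (b^2 P + S),  with b = 1 for F1.

Micro-averages pool the per-class TP/FP/TN/FN counts before applying a
formula; macro-averages are unweighted means of the per-class metrics.
For single-label multi-class predictions micro precision, micro
sensitivity and overall accuracy coincide.

The no-information rate (NIR) — the frequency of the most common true
class — is the accuracy of a constant classifier and serves as the null
of a one-tailed exact binomial test on the number of correct predictions.
ROC curves sweep a decision threshold over each class's score; the area
is computed by the trapezoid rule over the exact threshold set (sorted
unique scores plus sentinels), which equals the pairwise-concordance
(rank-sum) statistic with ties counted one half.

Cross-validation is stratified; fold summaries are reported as
mean +/- 95% CI using the t distribution with k-1 degrees of freedom,
appropriate at the usual k = 10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "class_metrics",
    "f1",
    "micro_macro",
    "nir",
    "binomial_vs_nir",
    "roc_auc",
    "cross_validate",
    "CLINICAL_VALIDATION_TABLE",
]

#: Published per-class validation metrics (10-fold cross-validated means)
#: of the clinical deep-learning study on 1005 BPPV patients whose grid
#: methodology this package re-implements.  Used as reference input for
#: arithmetic self-checks (macro averaging, F1 recomputation); the CI
#: half-widths of the publication are not reproduced here.
CLINICAL_VALIDATION_TABLE = pd.DataFrame(
    {
        "precision":   [0.888, 0.753, 0.837, 0.771, 0.800, 0.853, 0.775, 0.707],
        "sensitivity": [0.560, 0.882, 0.916, 0.941, 0.957, 0.934, 0.614, 0.663],
        "specificity": [0.985, 0.952, 0.970, 0.982, 0.967, 0.973, 0.986, 0.956],
        "f1":          [0.686, 0.813, 0.875, 0.847, 0.871, 0.891, 0.685, 0.684],
        "n":           [179, 144, 146, 61, 122, 142, 73, 138],
    },
    index=[
        "psc_right", "psc_left",
        "lsc_geo_right", "lsc_geo_left",
        "lsc_ageo_right", "lsc_ageo_left",
        "asc_right", "asc_left",
    ],
)


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = truth, columns = prediction."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be K x K matching labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = c.astype(np.int64)
        self.labels = tuple(self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, cls) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, FN, TN) for one class."""
        i = self.labels.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(truth: Sequence, predicted: Sequence, labels: Sequence | None = None) -> ConfusionMatrix:
    """Tally a confusion matrix; unknown labels raise."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if labels is None:
        labels = sorted(set(truth) | set(predicted))
    labels = tuple(labels)
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; metric defined as 0", name)
        return 0.0
    return num / den


def class_metrics(cm: ConfusionMatrix, cls) -> dict[str, float]:
    """One-vs-rest precision/sensitivity/specificity/FPR/accuracy of a class."""
    tp, fp, fn, tn = cm.ovr_counts(cls)
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "fpr": 1.0 - specificity,
        "accuracy": _safe_div(tp + tn, tp + fp + tn + fn, "accuracy"),
        "support": tp + fn,
    }


def f1(precision: float, sensitivity: float, beta: float = 1.0) -> float:
    """F-beta score; 0 when both inputs are 0."""
    if not (0 <= precision <= 1 and 0 <= sensitivity <= 1):
        raise ValueError("precision and sensitivity must lie in [0, 1]")
    den = beta**2 * precision + sensitivity
    if den == 0:
        return 0.0
    return (1 + beta**2) * precision * sensitivity / den


def micro_macro(cm: ConfusionMatrix) -> dict[str, float]:
    """Aggregate metrics: overall accuracy, micro- and macro-averages."""
    per = {c: class_metrics(cm, c) for c in cm.labels}
    for c in cm.labels:
        per[c]["f1"] = f1(per[c]["precision"], per[c]["sensitivity"])
    pooled = np.array([cm.ovr_counts(c) for c in cm.labels]).sum(axis=0)
    tp, fp, fn, tn = (int(v) for v in pooled)
    micro_p = _safe_div(tp, tp + fp, "micro precision")
    micro_s = _safe_div(tp, tp + fn, "micro sensitivity")
    micro_sp = _safe_div(tn, tn + fp, "micro specificity")
    out = {
        "accuracy": _safe_div(int(np.trace(cm.counts)), cm.total, "accuracy"),
        "micro_precision": micro_p,
        "micro_sensitivity": micro_s,
        "micro_specificity": micro_sp,
        "micro_fpr": 1.0 - micro_sp,
        "micro_f1": f1(micro_p, micro_s),
    }
    for name in ("precision", "sensitivity", "specificity", "fpr", "f1"):
        out[f"macro_{name}"] = float(np.mean([per[c][name] for c in cm.labels]))
    return out


def nir(truth: Sequence) -> float:
    """No-information rate: frequency of the most common true class."""
    truth = list(truth)
    if not truth:
        raise ValueError("empty label sequence")
    _, counts = np.unique(truth, return_counts=True)
    return float(counts.max() / len(truth))


def binomial_vs_nir(correct: int, total: int, nir_rate: float) -> float:
    """One-tailed exact binomial p-value: P(X >= correct), X ~ Bin(total, NIR)."""
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    if not 0.0 <= nir_rate <= 1.0:
        raise ValueError("NIR must lie in [0, 1]")
    # exact tail sum via the regularized incomplete beta (scipy's sf)
    return float(stats.binom.sf(correct - 1, total, nir_rate))


def _binary_roc(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points over the exact threshold set; trapezoid area."""
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    pos, neg = int(y.sum()), int((~y).sum())
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        call = s >= thr
        tpr[i] = (call & y).sum() / pos if pos else np.nan
        fpr[i] = (call & ~y).sum() / neg if neg else np.nan
    area = float(np.trapezoid(tpr, fpr))
    return thresholds, fpr, tpr, area


def roc_auc(
    scores: np.ndarray,
    truth: Sequence,
    labels: Sequence,
    mode: str = "macro",
) -> tuple[dict, float]:
    """One-vs-rest ROC analysis of per-sample per-class scores.

    ``scores`` has shape (N, K) aligned with ``labels``.  Returns
    ``(curves, area)`` where ``curves`` maps class (or ``"micro"``) to a
    (thresholds, fpr, tpr) triple.  In ``per_class`` mode the area is a
    dict per class; single-class truth makes a class's curve undefined and
    its area NaN (flagged by a warning).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(list(truth))
    labels = list(labels)
    if scores.shape != (len(truth), len(labels)):
        raise ValueError("scores must have shape (n_samples, n_classes)")
    if mode not in ("per_class", "micro", "macro"):
        raise ValueError(f"unknown mode {mode!r}")
    curves: dict = {}
    areas: dict = {}
    if mode == "micro":
        y = np.concatenate([(truth == l) for l in labels])
        s = scores.ravel(order="F")
        thr, fp, tp, area = _binary_roc(y, s)
        curves["micro"] = (thr, fp, tp)
        return curves, area
    for k, l in enumerate(labels):
        y = truth == l
        if y.all() or not y.any():
            logger.warning("class %r has single-class truth; AUROC undefined", l)
            areas[l] = float("nan")
            continue
        thr, fp, tp, area = _binary_roc(y, scores[:, k])
        curves[l] = (thr, fp, tp)
        areas[l] = area
    if mode == "per_class":
        return curves, areas
    vals = [a for a in areas.values() if not math.isnan(a)]
    return curves, float(np.mean(vals)) if vals else float("nan")


@dataclass
class MetricsReport:
    """Cross-validated metrics: per-fold values and mean +/- 95% CI."""

    folds: list[dict[str, float]]
    summary: pd.DataFrame  # index metric, columns mean / ci95_half
    per_class: pd.DataFrame  # mean per-class metrics across folds

    def mean(self, metric: str) -> float:
        return float(self.summary.loc[metric, "mean"])

    def ci95(self, metric: str) -> float:
        return float(self.summary.loc[metric, "ci95_half"])


def cross_validate(
    grids: np.ndarray,
    labels_idx: np.ndarray,
    class_labels: Sequence,
    pipeline: Callable,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of a classification pipeline.

    ``pipeline(train_grids, train_labels, test_grids)`` must return
    ``(predicted_indices, scores_or_None)``; scores, when given, are (N, K)
    class scores used for AUROC.  Fold assignment is a pure function of
    the seed.  The CI half-width is ``t(0.975, k-1) * SD / sqrt(k)``.
    """
    from sklearn.model_selection import StratifiedKFold

    labels_idx = np.asarray(labels_idx)
    counts = np.bincount(labels_idx, minlength=len(class_labels))
    if k < 2:
        raise ValueError("k must be >= 2")
    if counts.min() < k:
        raise ValueError("every class needs at least k samples for k folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[dict[str, float]] = []
    per_class_rows = []
    for tr, te in skf.split(grids, labels_idx):
        pred, scores = pipeline(grids[tr], labels_idx[tr], grids[te])
        cm = confusion(labels_idx[te].tolist(), list(pred), labels=range(len(class_labels)))
        agg = micro_macro(cm)
        agg["nir"] = nir(labels_idx[te].tolist())
        agg["binomial_p"] = binomial_vs_nir(
            int(np.trace(cm.counts)), cm.total, agg["nir"]
        )
        if scores is not None:
            _, agg["macro_auroc"] = roc_auc(scores, labels_idx[te], range(len(class_labels)), "macro")
            _, agg["micro_auroc"] = roc_auc(scores, labels_idx[te], range(len(class_labels)), "micro")
        folds.append(agg)
        per_class_rows.append(
            pd.DataFrame({c: class_metrics(cm, i) for i, c in enumerate(class_labels)}).T
        )
    metrics = folds[0].keys()
    rows = {}
    tcrit = stats.t.ppf(0.975, k - 1)
    for m in metrics:
        vals = np.array([f[m] for f in folds], dtype=float)
        rows[m] = {
            "mean": vals.mean(),
            "ci95_half": float(tcrit * vals.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0,
        }
    summary = pd.DataFrame(rows).T
    per_class = sum(per_class_rows) / len(per_class_rows)
    return MetricsReport(folds, summary, per_class)
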