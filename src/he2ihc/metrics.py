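"""Evaluation statistics: confusion matrix, per-class precision/recall/F1,
accuracy, and the product-moment (Pearson) correlation used for the
agreement analysis between H&E-derived and IHC-derived quantification.

Conventions: confusion-matrix rows are actual classes and columns predicted
classes; per class c, TP = M[c, c], FP = column sum - TP, FN = row sum - TP,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, and
accuracy = trace/total.  A class with a zero denominator reports 0 and is
flagged rather than raising, so batch evaluation always completes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassReport",
    "confusion_matrix",
    "classification_report",
    "pearson_r",
    "agreement_analysis",
]

_CLASS_NAMES = ("Negative", "Positive", "Background")


def _check_labels(actual, predicted, n_classes):
    actual = np.asarray(actual, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if actual.shape != predicted.shape:
        raise ValueError(f"length mismatch: {actual.shape} vs {predicted.shape}")
    for name, arr in (("actual", actual), ("predicted", predicted)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    return actual, predicted


@dataclass(frozen=True)
class ConfusionMatrix:
    matrix: np.ndarray  # (n, n) int; rows = actual, cols = predicted

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix) / self.total) if self.total else 0.0


def confusion_matrix(actual, predicted, n_classes: int = 3) -> ConfusionMatrix:
    actual, predicted = _check_labels(actual, predicted, n_classes)
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (actual, predicted), 1)
    return ConfusionMatrix(m)


@dataclass(frozen=True)
class ClassReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    zero_denominator: np.ndarray  # per class: any undefined metric reported as 0
    confusion: ConfusionMatrix

    def to_frame(self) -> pd.DataFrame:
        """Tabular report with per-class rows plus macro and support-weighted
        averages (both are given; reports in the literature often leave
        ambiguous which one their "avg" row means)."""
        w = self.support / self.support.sum() if self.support.sum() else self.support
        rows = {
            name: (self.precision[i], self.recall[i], self.f1[i], int(self.support[i]))
            for i, name in enumerate(_CLASS_NAMES[: len(self.precision)])
        }
        rows["Macro avg"] = (
            self.precision.mean(),
            self.recall.mean(),
            self.f1.mean(),
            int(self.support.sum()),
        )
        rows["Weighted avg"] = (
            float(self.precision @ w),
            float(self.recall @ w),
            float(self.f1 @ w),
            int(self.support.sum()),
        )
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["Precision", "Recall", "f1-score", "Support"]
        )


def classification_report(actual, predicted, n_classes: int = 3) -> ClassReport:
    cm = confusion_matrix(actual, predicted, n_classes)
    m = cm.matrix
    tp = np.diag(m).astype(np.float64)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    flags = np.zeros(n_classes, dtype=bool)

    def _safe(num, den):
        out = np.zeros(n_classes)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        flags[~ok] = True
        return out

    precision = _safe(tp, tp + fp)
    recall = _safe(tp, tp + fn)
    f1 = _safe(2 * precision * recall, precision + recall)
    return ClassReport(precision, recall, f1, cm.supports, cm.accuracy, flags, cm)


def pearson_r(x, y) -> float:
    """Product-moment correlation r = Cov(X, Y) / sqrt(Var[X] Var[Y]).

    Undefined (NaN, with a warning) when either input has zero variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("pearson_r needs two equal-length 1-d arrays of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = (xc * xc).mean()
    vy = (yc * yc).mean()
    if vx == 0.0 or vy == 0.0:
        warnings.warn("pearson_r undefined: an input has zero variance")
        return float("nan")
    return float((xc * yc).mean() / np.sqrt(vx * vy))


def agreement_analysis(quant_table: pd.DataFrame, n_bins: int = 10) -> dict:
    """Correlation of D_pos, D_neg and R_pos between H&E- and IHC-derived
    quantification, plus per-source frequency histograms of each index.

    ``quant_table`` is the long table from ``paired_quantification``.  ROIs
    where an index is undefined (NaN) in either source are dropped from that
    index's correlation.
    """
    he = quant_table[quant_table["source"] == "he"].set_index("roi_id")
    ihc = quant_table[quant_table["source"] == "ihc"].set_index("roi_id")
    if len(he) != len(ihc) or len(he) < 2:
        raise ValueError("need at least 2 paired ROIs with both sources")
    out: dict = {"n_pairs": len(he), "correlations": {}, "histograms": {}}
    for index in ("D_pos", "D_neg", "R_pos"):
        x = he[index].to_numpy()
        y = ihc.loc[he.index, index].to_numpy()
        keep = np.isfinite(x) & np.isfinite(y)
        out["correlations"][index] = (
            pearson_r(x[keep], y[keep]) if keep.sum() >= 2 else float("nan")
        )
        out["histograms"][index] = {}
        for source, values in (("he", x), ("ihc", y)):
            counts, edges = np.histogram(values[np.isfinite(values)], bins=n_bins, range=(0, 1))
            out["histograms"][index][source] = {"counts": counts, "bin_edges": edges}
    return out
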