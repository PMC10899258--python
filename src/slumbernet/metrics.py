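"""Evaluation metrics for three-stage sleep scoring.

Per-stage metrics are computed one-vs-rest from the 3x3 confusion
matrix (rows = true stage, columns = predicted, order W/N/R): accuracy,
precision, recall and F1 as percentages, and a per-stage Cohen's kappa
from the collapsed 2x2 table. Overall metrics include the full-matrix
kappa, categorical cross-entropy, explained variance, and the
cross-weighted overall precision/recall/F1 used when comparing scoring
models: overall precision is the recall-weighted mean of the per-stage
precisions, overall recall the precision-weighted mean of the recalls,
and overall F1 their harmonic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import STAGES

STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (3, 3) ints; rows true, columns predicted, order W/N/R

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, stage: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one stage against the rest."""
        i = STAGE_INDEX[stage]
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(true, pred) -> ConfusionMatrix:
    """Count matrix over stage codes or integer classes (0=W, 1=N, 2=R)."""
    t = _as_indices(true)
    p = _as_indices(pred)
    if t.shape != p.shape:
        raise ValueError("true and predicted sequences differ in length")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def per_class_metrics(cm: ConfusionMatrix, stage: str) -> dict[str, float]:
    """One-vs-rest accuracy/precision/recall/F1 (percent) for one stage.

    Undefined ratios (zero denominators) are reported as 0 with a warning
    so batch evaluation stays total.
    """
    tp, fp, fn, tn = cm.one_vs_rest(stage)
    precision = _safe_div(tp, tp + fp, f"{stage}: no positive predictions")
    recall = _safe_div(tp, tp + fn, f"{stage}: no positive instances")
    accuracy = _safe_div(tp + tn, cm.total, "empty confusion matrix")
    f1 = _safe_div(2 * precision * recall, precision + recall, f"{stage}: P + R = 0")
    return {
        "accuracy": 100.0 * accuracy,
        "precision": 100.0 * precision,
        "recall": 100.0 * recall,
        "f1": 100.0 * f1,
    }


def cohens_kappa(counts: np.ndarray) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) for a square count table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    p_o = np.trace(counts) / n
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / n ** 2
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_kappa(cm: ConfusionMatrix, stage: str) -> float:
    """Cohen's kappa on the stage-vs-rest 2x2 collapse of the matrix."""
    tp, fp, fn, tn = cm.one_vs_rest(stage)
    return cohens_kappa(np.array([[tp, fn], [fp, tn]]))


def categorical_cross_entropy(true_onehot: np.ndarray, probs: np.ndarray,
                              eps: float = 1e-12) -> float:
    """Mean over samples of -sum_i y_i ln(p_i), with probabilities clipped."""
    true_onehot = np.asarray(true_onehot, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if true_onehot.shape != probs.shape:
        raise ValueError("shape mismatch between labels and probabilities")
    p = np.clip(probs, eps, 1.0)
    return float(-(true_onehot * np.log(p)).sum(axis=1).mean())


def explained_variance(true_values, predicted_values) -> float:
    """1 - Var(y - yhat) / Var(y)."""
    y = np.asarray(true_values, dtype=float)
    yhat = np.asarray(predicted_values, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    var_y = y.var()
    if var_y == 0:
        raise ValueError("true values have zero variance; explained variance undefined")
    return float(1.0 - (y - yhat).var() / var_y)


def overall_weighted_metrics(precision: np.ndarray, recall: np.ndarray
                             ) -> tuple[float, float, float]:
    """Cross-weighted overall (precision, recall, F1) from per-stage values (%).

    Each stage's precision is weighted by its recall and vice versa, so
    stages with more actual or predicted occurrences dominate; overall F1
    is the harmonic mean of the two overall values.
    """
    p = np.asarray(precision, dtype=float)
    r = np.asarray(recall, dtype=float)
    if p.shape != (3,) or r.shape != (3,):
        raise ValueError("need per-stage 3-vectors")
    if r.sum() == 0 or p.sum() == 0:
        raise ValueError("all-zero weights")
    overall_p = float((p * r).sum() / r.sum())
    overall_r = float((r * p).sum() / p.sum())
    overall_f1 = 2.0 * overall_p * overall_r / (overall_p + overall_r)
    return overall_p, overall_r, overall_f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units in as out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def stage_metrics_row(cm: ConfusionMatrix) -> dict[str, float]:
    """All per-stage metrics plus overall kappa, as one flat mapping."""
    row: dict[str, float] = {}
    for s in STAGES:
        m = per_class_metrics(cm, s)
        row.update({f"{s}_{k}": v for k, v in m.items()})
        row[f"{s}_kappa"] = per_class_kappa(cm, s)
    row["overall_accuracy"] = 100.0 * np.trace(cm.counts) / cm.total
    row["overall_kappa"] = cohens_kappa(cm.counts)
    return row


def fold_summary(fold_rows: pd.DataFrame) -> pd.DataFrame:
    """Append columnwise mean and SEM (sample SD / sqrt(n)) rows to a fold table."""
    if len(fold_rows) < 2:
        raise ValueError("need at least two fold rows to summarize")
    num = fold_rows.select_dtypes("number")
    mean = num.mean()
    sem = num.std(ddof=1) / np.sqrt(len(num))
    out = fold_rows.copy()
    out.loc["mean"] = mean
    out.loc["sem"] = sem
    return out


def _as_indices(seq) -> np.ndarray:
    arr = np.asarray(seq)
    if arr.dtype.kind in "iu":
        if np.any((arr < 0) | (arr > 2)):
            raise ValueError("class indices must be 0, 1 or 2")
        return arr.astype(int)
    try:
        return np.array([STAGE_INDEX[str(s)] for s in arr])
    except KeyError as e:
        raise ValueError(f"unknown stage code {e}") from None


def _safe_div(num: float, den: float, context: str) -> float:
    if den == 0:
        warnings.warn(f"undefined metric ({context}); reporting 0", stacklevel=3)
        return 0.0
    return num / den
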