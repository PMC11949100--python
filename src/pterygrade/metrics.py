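"""Segmentation-quality and grading-agreement metrics.

Per-class segmentation metrics are one-vs-rest pixel counts: precision
TP/(TP+FP), recall TP/(TP+FN), IoU TP/(TP+FP+FN) and Dice
2TP/(2TP+FP+FN), so Dice = 2*IoU/(1+IoU) always holds.  Grading
agreement is summarised by a 3x3 confusion matrix (rows = expert grade,
columns = predicted), overall accuracy, the weighted F1 score (per-class
F1 weighted by expert-class prevalence) and Cohen's kappa
(P_o - P_e)/(1 - P_e) with chance agreement P_e = sum_k row_k*col_k/N^2.

The diameter sweep re-grades a fixed case set for every reference corneal
diameter on a grid; since pupil coverage is diameter-independent, only
the grade-1/grade-2 boundary can move across the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grading import (
    AssessmentConfig,
    GRADE_DEPTH_THRESHOLD_MM,
    assess_image,
)
from .phantom import LabelMask

GRADES = (1, 2, 3)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest pixel metrics for a single class."""

    class_code: int
    tp: int
    fp: int
    fn: int
    iou: float
    dice: float
    precision: float
    recall: float
    undefined: bool = False


@dataclass(frozen=True)
class GradingSummary:
    """Agreement between predicted and expert grades."""

    confusion: np.ndarray  # 3x3, rows = expert, cols = predicted
    accuracy: float
    weighted_f1: float
    kappa: float
    reference_diameter_mm: float


def _safe_ratio(num: int, den: int, both_empty: bool) -> tuple[float, bool]:
    if den == 0:
        return (1.0 if both_empty else 0.0), True
    return num / den, False


def per_class_metrics(pred: LabelMask, truth: LabelMask,
                      class_code: int) -> ClassMetrics:
    """Pixelwise TP/FP/FN and overlap metrics for one class.

    When a metric's denominator is zero it reports 1 if the class is
    absent from both masks and 0 otherwise, flagged as undefined.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == class_code
    t = truth == class_code
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    both_empty = not p.any() and not t.any()

    iou, u1 = _safe_ratio(tp, tp + fp + fn, both_empty)
    dice, u2 = _safe_ratio(2 * tp, 2 * tp + fp + fn, both_empty)
    precision, u3 = _safe_ratio(tp, tp + fp, both_empty)
    recall, u4 = _safe_ratio(tp, tp + fn, both_empty)
    return ClassMetrics(class_code=int(class_code), tp=tp, fp=fp, fn=fn,
                        iou=iou, dice=dice, precision=precision, recall=recall,
                        undefined=u1 or u2 or u3 or u4)


def confusion_matrix(pred_grades: Sequence[int],
                     expert_grades: Sequence[int]) -> np.ndarray:
    """3x3 count matrix with rows = expert grade, columns = predicted."""
    conf = np.zeros((3, 3), dtype=int)
    for p, e in zip(pred_grades, expert_grades, strict=True):
        if p not in GRADES or e not in GRADES:
            raise ValueError(f"grades must be in {GRADES}, got pred={p} expert={e}")
        conf[e - 1, p - 1] += 1
    return conf


def summary_from_confusion(conf: np.ndarray,
                           reference_diameter_mm: float) -> GradingSummary:
    conf = np.asarray(conf, dtype=float)
    n = conf.sum()
    accuracy = float(np.trace(conf) / n)

    # per-class F1 over expert classes; a class absent from both graders
    # contributes F1 = 1 but carries zero prevalence weight anyway
    f1 = np.zeros(3)
    for i in range(3):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        den = 2 * tp + fp + fn
        f1[i] = 1.0 if den == 0 else 2 * tp / den
    weights = conf.sum(axis=1) / n
    weighted_f1 = float(np.dot(weights, f1))

    p_o = accuracy
    p_e = float(np.dot(conf.sum(axis=1), conf.sum(axis=0)) / n**2)
    kappa = 1.0 if p_e == 1.0 else float((p_o - p_e) / (1.0 - p_e))
    return GradingSummary(confusion=conf.astype(int), accuracy=accuracy,
                          weighted_f1=weighted_f1, kappa=kappa,
                          reference_diameter_mm=reference_diameter_mm)


def grading_summary(pred_grades: Sequence[int], expert_grades: Sequence[int],
                    reference_diameter_mm: float = 11.5) -> GradingSummary:
    """Confusion matrix, accuracy, weighted F1 and Cohen's kappa."""
    if len(pred_grades) == 0 or len(expert_grades) == 0:
        raise ValueError("grade lists must be non-empty")
    conf = confusion_matrix(pred_grades, expert_grades)
    return summary_from_confusion(conf, reference_diameter_mm)


def diameter_grid(l_min: float = 11.5, l_max: float = 12.5,
                  step: float = 0.1) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((l_max - l_min) / step)) + 1
    return np.round(l_min + step * np.arange(n), 10)


def sweep_case_grades(cases: Sequence[tuple[LabelMask, int]],
                      l_min: float = 11.5, l_max: float = 12.5,
                      step: float = 0.1,
                      config: AssessmentConfig = AssessmentConfig(),
                      ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-case predicted grades across the diameter grid.

    Each mask is assessed once (the fits, beta and pupil coverage do not
    depend on the reference diameter); only the depth-in-mm thresholding
    is redone per diameter.  Returns ``(diameters, grades, experts)``
    where ``grades[i, j]`` is the grade of case ``i`` at diameter ``j``.
    Grade-3 decisions are diameter-independent by construction, so only
    the grade-1/2 boundary varies across columns.
    """
    if len(cases) == 0:
        raise ValueError("need at least one case")
    diameters = diameter_grid(l_min, l_max, step)
    grades = np.empty((len(cases), len(diameters)), dtype=int)
    experts = []
    for i, (mask, expert) in enumerate(cases):
        res = assess_image(mask, config)
        experts.append(int(expert))
        if res.metrics.pupil_covered:
            grades[i, :] = 3
        else:
            grades[i, :] = np.where(
                res.metrics.beta * diameters > GRADE_DEPTH_THRESHOLD_MM, 2, 1)
    return diameters, grades, experts


def diameter_sweep(cases: Sequence[tuple[LabelMask, int]],
                   l_min: float = 11.5, l_max: float = 12.5, step: float = 0.1,
                   config: AssessmentConfig = AssessmentConfig(),
                   ) -> list[GradingSummary]:
    """One :class:`GradingSummary` per reference diameter on the grid."""
    diameters, grades, experts = sweep_case_grades(cases, l_min, l_max, step,
                                                   config)
    return [grading_summary(list(grades[:, j]), experts, float(L))
            for j, L in enumerate(diameters)]


def sweep_table(summaries: Sequence[GradingSummary]) -> pd.DataFrame:
    """Sweep results as a tidy table, one row per reference diameter."""
    return pd.DataFrame(
        {
            "reference_diameter_mm": [s.reference_diameter_mm for s in summaries],
            "accuracy": [s.accuracy for s in summaries],
            "weighted_f1": [s.weighted_f1 for s in summaries],
            "kappa": [s.kappa for s in summaries],
        }
    )
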