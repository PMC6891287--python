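"""Confusion-count metrics, ROC/AUROC and macro-averaging over six contrasts.

Precision = TP/(TP+FP), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)
and accuracy = (TP+TN)/total; metrics with an empty denominator are reported
as ``None`` (undefined), never silently 0.  ROC curves place thresholds at
unique score values (ties grouped), and AUROC is the trapezoidal area, which
equals the Mann-Whitney concordance probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io_gal import EVENT_NAMES

METRIC_NAMES = ("precision", "sensitivity", "specificity", "accuracy")


class DegenerateError(ValueError):
    """ROC needs both classes present in the truth labels."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Joint-outcome counts of binary truth vs binary prediction."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for v in (y_true, y_pred):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """The four classification metrics; ``None`` where a denominator is zero."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "precision": ratio(c.TP, c.TP + c.FP),
        "sensitivity": ratio(c.TP, c.TP + c.FN),
        "specificity": ratio(c.TN, c.TN + c.FP),
        "accuracy": ratio(c.TP + c.TN, c.total),
    }


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float


def roc_auroc(y_true, scores) -> ROCCurve:
    """ROC curve over unique-score thresholds and its trapezoidal area."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(y_true)) < 2:
        raise DegenerateError("ROC requires both classes in the truth labels")
    fpr, tpr, thr = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr,
                    auroc=float(np.trapezoid(tpr, fpr)))


@dataclass
class EvalReport:
    """Per-contrast metrics and ROC plus unweighted macro averages."""

    per_contrast: dict[str, dict] = field(default_factory=dict)
    macro: dict[str, float | None] = field(default_factory=dict)
    n_images: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"contrast": name, **{m: vals[m] for m in METRIC_NAMES},
             "auroc": vals["auroc"], "n": vals["n"]}
            for name, vals in self.per_contrast.items()
        ]
        rows.append({"contrast": "macro", **self.macro, "n": self.n_images})
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "per_contrast": {
                k: {m: v[m] for m in (*METRIC_NAMES, "auroc", "n")}
                for k, v in self.per_contrast.items()
            },
            "macro": self.macro,
            "n_images": self.n_images,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def macro_report(per_contrast: dict[str, tuple[dict, ROCCurve, int]]) -> EvalReport:
    """Combine six per-contrast (metrics, ROC, n) entries into one report.

    Macro averages are unweighted means over the six contrasts; a metric that
    is undefined in any contrast stays undefined in the average.
    """
    missing = [n for n in EVENT_NAMES if n not in per_contrast]
    if missing:
        raise ValueError(f"report lacks contrasts: {missing}")
    report = EvalReport()
    for name in EVENT_NAMES:
        m, roc, n = per_contrast[name]
        report.per_contrast[name] = {**m, "auroc": roc.auroc, "roc": roc, "n": n}
        report.n_images += n
    for key in (*METRIC_NAMES, "auroc"):
        vals = [report.per_contrast[n][key] for n in EVENT_NAMES]
        report.macro[key] = None if any(v is None for v in vals) else float(np.mean(vals))
    return report


def evaluate_contrast(y_true, scores, threshold: float = 0.5) -> tuple[dict, ROCCurve, int]:
    """Metrics at a fixed operating point plus the full ROC for one contrast."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = (scores >= threshold).astype(int)
    return metrics(confusion(y_true, y_pred)), roc_auroc(y_true, scores), len(y_true)
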