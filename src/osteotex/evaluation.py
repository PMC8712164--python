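"""Confusion matrices, classification metrics, and feature summaries.

Positive-class convention throughout: cancerous = +1. Metrics are
reported as percentages; a metric whose denominator is zero is reported
as ``None`` (undefined) rather than silently zero-filled, so degenerate
runs cannot masquerade as perfect ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "confusion", "metrics", "format_metrics",
           "boxplot_table"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with cancerous (+1) as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count prediction outcomes; labels must be in {+1, -1}."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError(
            f"length mismatch: {t.shape[0]} true vs {p.shape[0]} predicted"
        )
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        bad = set(np.unique(arr)) - {1, -1}
        if bad:
            raise ValueError(f"{name} contains labels outside {{+1,-1}}: {bad}")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == -1)).sum()),
        fp=int(((t == -1) & (p == 1)).sum()),
        tn=int(((t == -1) & (p == -1)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> dict[str, Optional[float]]:
    """Accuracy, precision, recall and F1 as percentages.

    accuracy  = 100 (tp + tn) / total
    precision = 100 tp / (tp + fp)
    recall    = 100 tp / (tp + fn)
    f1        = 2 precision recall / (precision + recall)

    Any metric with a zero denominator is ``None``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    precision = 100.0 * cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    recall = 100.0 * cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1}


def format_metrics(m: dict[str, Optional[float]]) -> dict[str, str]:
    """Render metrics to two decimal places; undefined stays 'undefined'."""
    return {
        k: "undefined" if v is None else f"{v:.2f}" for k, v in m.items()
    }


def boxplot_table(
    features: Sequence, with_hog_row: bool = True
) -> pd.DataFrame:
    """Five-number summaries (min/Q1/median/Q3/max) of each scalar
    feature, plus the HOG-mean scalar when descriptors are present.

    Quartiles use linear interpolation. One row per feature.
    """
    from .classification import SCALAR_FEATURES  # local import avoids a cycle

    if not features:
        raise ValueError("empty feature set")
    rows = {}
    for name in SCALAR_FEATURES:
        rows[name] = [fv.scalars[name] for fv in features]
    if with_hog_row and all(fv.hog is not None for fv in features):
        rows["hog_mean"] = [float(np.mean(fv.hog)) for fv in features]
    out = {}
    for name, vals in rows.items():
        v = np.asarray(vals, dtype=float)
        out[name] = {
            "min": v.min(),
            "q1": np.percentile(v, 25),
            "median": np.percentile(v, 50),
            "q3": np.percentile(v, 75),
            "max": v.max(),
        }
    return pd.DataFrame(out).T[["min", "q1", "median", "q3", "max"]]
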