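"""Metric suite: accuracy plus micro-averaged AUPR, AUC, precision,
recall and F1, and a per-event one-vs-rest score table.

Micro-averaging flattens the one-vs-rest binarized label matrix against
the flattened score matrix into a single binary problem before
computing ranking areas, and pools the argmax one-vs-rest confusion
counts for precision/recall/F1.  For single-label multiclass
predictions this makes micro precision, recall and F1 all coincide with
accuracy — a useful internal consistency identity.

AUPR is computed in its average-precision (step-wise interpolation)
form, the standard non-optimistic estimator; AUC handles score ties by
average rank.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_fscore_support,
    roc_auc_score,
)

__all__ = ["MetricReport", "compute_metrics", "per_event_scores"]

METRIC_FIELDS = (
    "acc",
    "aupr_micro",
    "auc_micro",
    "precision_micro",
    "recall_micro",
    "f1_micro",
)


@dataclass(frozen=True)
class MetricReport:
    """Accuracy and the five micro-averaged scores, each in [0, 1].

    Fields that are undefined on a degenerate input (e.g. AUC with a
    single-class truth vector) are ``None``.
    """

    acc: float | None
    aupr_micro: float | None
    auc_micro: float | None
    precision_micro: float | None
    recall_micro: float | None
    f1_micro: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def empty(cls) -> "MetricReport":
        return cls(*([None] * len(METRIC_FIELDS)))

    @classmethod
    def mean(cls, reports: list["MetricReport"]) -> "MetricReport":
        vals = {}
        for f in METRIC_FIELDS:
            xs = [getattr(r, f) for r in reports]
            vals[f] = None if any(x is None for x in xs) else float(np.mean(xs))
        return cls(**vals)

    def __str__(self) -> str:
        parts = [
            f"{f}={getattr(self, f):.4f}" if getattr(self, f) is not None else f"{f}=NA"
            for f in METRIC_FIELDS
        ]
        return "MetricReport(" + ", ".join(parts) + ")"


def _validate(true_labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(true_labels, int)
    s = np.asarray(scores, float)
    if s.ndim != 2 or len(y) != s.shape[0]:
        raise ValueError(f"scores must be (n_samples, n_classes); got {s.shape}")
    if y.min() < 0 or y.max() >= s.shape[1]:
        raise ValueError(
            f"labels must lie in [0, {s.shape[1]}), got range "
            f"[{y.min()}, {y.max()}]"
        )
    if not np.allclose(s.sum(axis=1), 1.0, atol=1e-4):
        raise ValueError("score rows must sum to 1")
    return y, s


def compute_metrics(true_labels: np.ndarray, score_matrix: np.ndarray) -> MetricReport:
    """Accuracy and micro-averaged AUPR/AUC/precision/recall/F1.

    ``score_matrix`` holds per-class probabilities (rows sum to 1);
    accuracy and the confusion-based micro scores use the row argmax.
    With a single-class truth vector the ranking areas are undefined
    and reported as ``None`` with a warning.
    """
    y, s = _validate(true_labels, score_matrix)
    n_classes = s.shape[1]
    pred = s.argmax(axis=1)
    acc = float((pred == y).mean())
    y_bin = np.zeros_like(s)
    y_bin[np.arange(len(y)), y] = 1.0
    if len(np.unique(y)) < 2:
        warnings.warn(
            "single-class truth vector: micro AUC/AUPR undefined", RuntimeWarning
        )
        aupr = auc = None
    else:
        aupr = float(average_precision_score(y_bin.ravel(), s.ravel()))
        auc = float(roc_auc_score(y_bin.ravel(), s.ravel()))
    p, r, f1, _ = precision_recall_fscore_support(
        y, pred, labels=np.arange(n_classes), average="micro", zero_division=0
    )
    return MetricReport(
        acc=acc,
        aupr_micro=aupr,
        auc_micro=auc,
        precision_micro=float(p),
        recall_micro=float(r),
        f1_micro=float(f1),
    )


def per_event_scores(
    true_labels: np.ndarray, score_matrix: np.ndarray
) -> pd.DataFrame:
    """Per-event one-vs-rest score table (the six metrics + their mean).

    For each event class ``e`` present in the truth vector: binary
    accuracy of the argmax decision ``pred == e`` against ``true == e``,
    one-vs-rest AUPR/AUC from the event's score column, and binary
    precision/recall/F1 with ``e`` as the positive class.  Events absent
    from the truth are included with ``defined=False`` and NaN scores.
    """
    y, s = _validate(true_labels, score_matrix)
    pred = s.argmax(axis=1)
    rows = []
    for e in range(s.shape[1]):
        pos = y == e
        if not pos.any():
            rows.append(
                {"event": e, "defined": False}
                | {m: np.nan for m in METRIC_FIELDS}
                | {"mean_score": np.nan, "support": 0}
            )
            continue
        pred_pos = pred == e
        tp = int((pred_pos & pos).sum())
        fp = int((pred_pos & ~pos).sum())
        fn = int((~pred_pos & pos).sum())
        acc = float((pred_pos == pos).mean())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn)
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if pos.all():
            aupr = auc = np.nan
        else:
            aupr = float(average_precision_score(pos, s[:, e]))
            auc = float(roc_auc_score(pos, s[:, e]))
        vals = {
            "acc": acc,
            "aupr_micro": aupr,
            "auc_micro": auc,
            "precision_micro": precision,
            "recall_micro": recall,
            "f1_micro": f1,
        }
        rows.append(
            {"event": e, "defined": True}
            | vals
            | {
                "mean_score": float(np.nanmean(list(vals.values()))),
                "support": int(pos.sum()),
            }
        )
    df = pd.DataFrame(rows)
    return df.rename(
        columns={
            "aupr_micro": "aupr",
            "auc_micro": "auc",
            "precision_micro": "precision",
            "recall_micro": "recall",
            "f1_micro": "f1",
        }
    )
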