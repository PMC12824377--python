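"""Pixel-level evaluation: confusion matrices and per-class accuracy.

Rows index the ground truth, columns the prediction.  Edge-truth pixels
are excluded by default (the confusion matrix covers the chemical classes
and background); the average accuracy is the unweighted (macro) mean of
the per-class recalls over the classes actually present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .materials import BACKGROUND, EDGE, CLASS_NAMES


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # [n_classes, n_classes]
    classes: List[int]  # class codes, row/col order

    def to_dataframe(self) -> pd.DataFrame:
        names = [CLASS_NAMES.get(c, str(c)) for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def save_png(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_dataframe()
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(df.values, cmap="Blues")
        ax.set_xticks(range(len(df)), df.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(df)), df.index)
        for i in range(len(df)):
            for j in range(len(df)):
                ax.text(j, i, str(df.values[i, j]), ha="center", va="center",
                        fontsize=8)
        ax.set_xlabel("prediction")
        ax.set_ylabel("ground truth")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion(pred: np.ndarray, truth: np.ndarray,
              include_edge: bool = False,
              classes: Optional[Sequence[int]] = None) -> ConfusionMatrix:
    """Pixel-level confusion over evaluated pixels.

    Edge-truth pixels are excluded unless ``include_edge``; predictions of
    Edge at evaluated pixels still appear in the Edge column."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if classes is None:
        classes = list(range(8)) + [BACKGROUND, EDGE]
    mask = np.ones(truth.shape, dtype=bool)
    if not include_edge:
        mask = truth != EDGE
    counts = _sk_confusion(truth[mask].ravel(), pred[mask].ravel(),
                           labels=list(classes))
    return ConfusionMatrix(counts.astype(np.int64), list(classes))


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall (diagonal over row sum); NaN for empty rows."""
    row_sums = cm.counts.sum(axis=1)
    out = np.full(len(cm.classes), np.nan)
    nonzero = row_sums > 0
    out[nonzero] = np.diag(cm.counts)[nonzero] / row_sums[nonzero]
    return out


def average_accuracy(cm: ConfusionMatrix,
                     include_classes: Optional[Sequence[int]] = None) -> float:
    """Unweighted mean of per-class recalls.

    Defaults to the chemical classes plus background (edge excluded);
    classes with no ground-truth pixels are dropped with a warning."""
    if include_classes is None:
        include_classes = list(range(8)) + [BACKGROUND]
    acc = per_class_accuracy(cm)
    vals = []
    for c in include_classes:
        i = cm.classes.index(c)
        if np.isnan(acc[i]):
            warnings.warn(f"class {CLASS_NAMES.get(c, c)} has no ground-truth "
                          "pixels; excluded from the average")
            continue
        vals.append(acc[i])
    if not vals:
        raise ValueError("no evaluable classes")
    return float(np.mean(vals))
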