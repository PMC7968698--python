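"""Confusion matrices and classification metrics in both category spaces.

Metrics follow the one-vs-rest reading: for each category, TP/TN/FP/FN are
taken from the confusion matrix treating that category against the rest,
and

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)
* F1        = 2 * precision * recall / (precision + recall)

Overall accuracy is the trace of the confusion matrix over its total.
Zero-denominator ratios are reported as 0 and flagged, never raised, so
batch evaluation always completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TrapDataset
from .imaging import write_image
from .labels import categories, label_index, merge_label


def confusion(true_labels, predicted_labels, space: int = 5) -> np.ndarray:
    """Count table ``C[a, b]`` = items with true label a predicted b.

    Labels are strings of the chosen space (5 computed or 4 biological
    categories), rows/columns in canonical order.
    """
    cats = categories(space)
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label sequences differ in length: {len(true_labels)} vs "
            f"{len(predicted_labels)}"
        )
    c = np.zeros((space, space), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        c[label_index(t, space), label_index(p, space)] += 1
    return c


@dataclass
class MetricsReport:
    """Per-category and overall metrics derived from one confusion matrix."""

    space: int
    per_category: pd.DataFrame     # index: category; accuracy/precision/recall/f1
    overall_accuracy: float
    macro_precision: float
    macro_recall: float
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.per_category.to_csv(path)

    def summary(self) -> str:
        lines = [
            f"{self.space}-category metrics "
            f"(overall accuracy {self.overall_accuracy:.4f})",
            self.per_category.round(4).to_string(),
            f"macro precision {self.macro_precision:.4f}  "
            f"macro recall {self.macro_recall:.4f}",
        ]
        if self.undefined:
            lines.append(f"zero-denominator metrics reported as 0: {self.undefined}")
        return "\n".join(lines)


def _safe_div(num: float, den: float, flag: tuple[str, str],
              undefined: list) -> float:
    if den == 0:
        undefined.append(flag)
        return 0.0
    return num / den


def metrics(c: np.ndarray) -> MetricsReport:
    """Compute the metrics report for a 5x5 or 4x4 confusion matrix."""
    c = np.asarray(c)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] not in (4, 5):
        raise ValueError(f"expected a 4x4 or 5x5 confusion matrix, got {c.shape}")
    if np.any(c < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = int(c.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    space = c.shape[0]
    cats = categories(space)
    undefined: list[tuple[str, str]] = []
    rows = {}
    for i, cat in enumerate(cats):
        tp = c[i, i]
        fp = c[:, i].sum() - tp
        fn = c[i, :].sum() - tp
        tn = total - tp - fp - fn
        precision = _safe_div(tp, tp + fp, (cat, "precision"), undefined)
        recall = _safe_div(tp, tp + fn, (cat, "recall"), undefined)
        f1 = _safe_div(2 * precision * recall, precision + recall,
                       (cat, "f1"), undefined)
        rows[cat] = {
            "accuracy": (tp + tn) / total,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    per_cat = pd.DataFrame(rows).T[["accuracy", "precision", "recall", "f1"]]
    return MetricsReport(
        space=space,
        per_category=per_cat,
        overall_accuracy=float(np.trace(c)) / total,
        macro_precision=float(per_cat["precision"].mean()),
        macro_recall=float(per_cat["recall"].mean()),
        undefined=undefined,
    )


def export_misclassified(dataset: TrapDataset, predicted5: list[str],
                         out_dir: str | Path) -> pd.DataFrame:
    """Write every image mispredicted in the biological 4-space.

    One row (and one PNG named ``i{idx}_{true}_as_{pred}.png``) per item
    whose merged prediction differs from its merged truth; returns the
    manifest and writes it as ``misclassified.csv``.
    """
    if len(predicted5) != len(dataset):
        raise ValueError("predictions do not match dataset length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (t5, p5) in enumerate(zip(dataset.labels, predicted5)):
        t4, p4 = merge_label(t5), merge_label(p5)
        if t4 == p4:
            continue
        name = f"i{i:05d}_{t4}_as_{p4}.png"
        write_image(dataset.images[i], out_dir / name)
        rows.append({"index": i, "true5": t5, "predicted5": p5,
                     "true4": t4, "predicted4": p4, "path": name})
    man = pd.DataFrame(rows, columns=["index", "true5", "predicted5",
                                      "true4", "predicted4", "path"])
    man.to_csv(out_dir / "misclassified.csv", index=False)
    return man
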