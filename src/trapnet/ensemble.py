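"""Validation-accuracy-weighted averaging of classifier probability vectors.

Single architectures show complementary error profiles on trap images, so
a convex combination of their predicted probability vectors — weighted by
each member's accuracy on the shared validation split — can beat every
member.  From three fitted models there are exactly four ensembles: the
three pairs and the full triple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .labels import merge_probs, CATEGORIES_4


@dataclass
class EnsembleModel:
    """Member predictors plus normalized nonnegative weights."""

    members: list                      # TrainingResult-like: .predict, .validation_accuracy
    weights: np.ndarray = field(default=None)
    name: str = ""

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.weights is None:
            accs = []
            for m in self.members:
                acc = getattr(m, "validation_accuracy", None)
                if acc is None:
                    raise ValueError("every member needs a recorded validation accuracy")
                accs.append(float(acc))
            accs = np.asarray(accs)
            if np.any(accs < 0):
                raise ValueError("validation accuracies must be nonnegative")
            if accs.sum() == 0:
                raise ValueError("all member validation accuracies are zero")
            self.weights = accs / accs.sum()
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.members):
                raise ValueError("one weight per member required")

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Weighted-average probability vectors over the 5 categories."""
        out = None
        for w, m in zip(self.weights, self.members):
            p = np.asarray(m.predict(images))
            if out is None:
                out = w * p
            elif p.shape != out.shape:
                raise ValueError(
                    f"member output shape {p.shape} does not match {out.shape}"
                )
            else:
                out += w * p
        return out

    def predict_labels4(self, images: np.ndarray) -> list[str]:
        """Biological 4-space predictions via probability merge then argmax."""
        p4 = merge_probs(self.predict(images))
        return [CATEGORIES_4[i] for i in np.argmax(p4, axis=1)]

    def save_spec(self, path: str | Path, member_paths: list[str] | None = None) -> None:
        spec = {
            "name": self.name,
            "weights": [float(w) for w in self.weights],
            "validation_accuracies": [
                float(getattr(m, "validation_accuracy", float("nan")))
                for m in self.members
            ],
            "member_checkpoints": member_paths or [],
        }
        Path(path).write_text(json.dumps(spec, indent=2))


def build_ensemble(members: list, name: str = "") -> EnsembleModel:
    """Weight members by validation accuracy, normalized to sum to 1."""
    return EnsembleModel(list(members), name=name)


def ensemble_predict(ensemble: EnsembleModel, images: np.ndarray) -> np.ndarray:
    return ensemble.predict(images)


def enumerate_ensembles(members: list) -> list[EnsembleModel]:
    """All four ensembles of exactly three members: the 3 pairs + the triple.

    Order is deterministic: pairs in index order, then the full triple.
    """
    if len(members) != 3:
        raise ValueError("expected exactly 3 members")
    out = []
    for size in (2, 3):
        for combo in combinations(range(3), size):
            out.append(
                build_ensemble(
                    [members[i] for i in combo],
                    name="+".join(str(i) for i in combo),
                )
            )
    return out
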