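"""Category spaces for trap images and the split/merge machinery between them.

Trap sub-images are labelled in two related spaces:

* the five *computed* categories used for training — ``nC`` (empty trap),
  ``mC`` (mother only), ``mduC`` (mother + daughter above), ``mddC``
  (mother + daughter below), ``exC`` (more than two cells);
* the four *biological* categories used for reporting — ``nC``, ``mC``,
  ``mdC``, ``exC`` — where the two daughter orientations collapse into a
  single mother-plus-daughter class ``mdC``.

Splitting the two-cell class by daughter orientation gives each computed
class a more homogeneous spatial pattern, which is easier for image
classifiers to learn; merging back afterwards restores the biologically
meaningful grouping.  This module fixes the canonical category orders and
provides the merge maps for labels, probability vectors and confusion
matrices.
"""

from __future__ import annotations

import numpy as np

#: Canonical order of the five computed categories.  All probability vectors
#: and confusion matrices over the 5-space use this order.
CATEGORIES_5: tuple[str, ...] = ("nC", "mC", "mduC", "mddC", "exC")

#: Canonical order of the four biological categories.
CATEGORIES_4: tuple[str, ...] = ("nC", "mC", "mdC", "exC")

#: Label-level merge map from the 5-space into the 4-space.
MERGE_MAP: dict[str, str] = {
    "nC": "nC",
    "mC": "mC",
    "mduC": "mdC",
    "mddC": "mdC",
    "exC": "exC",
}

_IDX5 = {c: i for i, c in enumerate(CATEGORIES_5)}
_IDX4 = {c: i for i, c in enumerate(CATEGORIES_4)}

_PROB_TOL = 1e-9


def categories(space: int) -> tuple[str, ...]:
    """Return the canonical category tuple for ``space`` (5 or 4)."""
    if space == 5:
        return CATEGORIES_5
    if space == 4:
        return CATEGORIES_4
    raise ValueError(f"unknown category space: {space!r} (expected 5 or 4)")


def label_index(label: str, space: int = 5) -> int:
    """Canonical index of ``label`` in the given space."""
    idx = _IDX5 if space == 5 else _IDX4 if space == 4 else None
    if idx is None:
        raise ValueError(f"unknown category space: {space!r}")
    try:
        return idx[label]
    except KeyError:
        raise ValueError(f"unknown label {label!r} for {space}-category space") from None


def merge_label(label: str) -> str:
    """Map a computed 5-space label onto its biological 4-space label.

    ``mddC`` and ``mduC`` (daughter below / above the mother) describe the
    same biological situation and both map to ``mdC``; the other labels map
    to themselves.
    """
    try:
        return MERGE_MAP[label]
    except KeyError:
        raise ValueError(f"unknown 5-category label: {label!r}") from None


def merge_probs(p: np.ndarray) -> np.ndarray:
    """Merge a probability vector over the 5 computed categories into 4.

    The ``mdC`` entry is the sum of the ``mduC`` and ``mddC`` entries; the
    remaining entries carry over.  Input must be a valid probability vector
    (nonnegative, summing to one within 1e-9); so is the output.

    Accepts a single vector of shape ``(5,)`` or a batch ``(n, 5)``.
    """
    p = np.asarray(p, dtype=float)
    squeeze = p.ndim == 1
    if squeeze:
        p = p[None, :]
    if p.ndim != 2 or p.shape[1] != 5:
        raise ValueError(f"expected shape (5,) or (n, 5), got {p.shape}")
    if np.any(p < -_PROB_TOL):
        raise ValueError("probability vector has negative entries")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability vector does not sum to 1")
    out = np.empty((p.shape[0], 4), dtype=float)
    out[:, _IDX4["nC"]] = p[:, _IDX5["nC"]]
    out[:, _IDX4["mC"]] = p[:, _IDX5["mC"]]
    out[:, _IDX4["mdC"]] = p[:, _IDX5["mduC"]] + p[:, _IDX5["mddC"]]
    out[:, _IDX4["exC"]] = p[:, _IDX5["exC"]]
    return out[0] if squeeze else out


def reduce_confusion(c5: np.ndarray) -> np.ndarray:
    """Reduce a 5-space confusion matrix to the 4 biological categories.

    The ``mduC`` and ``mddC`` rows are summed, as are the columns, so
    within-pair confusions become correct ``mdC`` calls.  The grand total is
    preserved.
    """
    c5 = np.asarray(c5)
    if c5.shape != (5, 5):
        raise ValueError(f"expected a 5x5 confusion matrix, got {c5.shape}")
    if np.any(c5 < 0):
        raise ValueError("confusion counts must be nonnegative")
    groups = [
        [_IDX5["nC"]],
        [_IDX5["mC"]],
        [_IDX5["mduC"], _IDX5["mddC"]],
        [_IDX5["exC"]],
    ]
    c4 = np.zeros((4, 4), dtype=c5.dtype)
    for a, rows in enumerate(groups):
        for b, cols in enumerate(groups):
            c4[a, b] = c5[np.ix_(rows, cols)].sum()
    return c4


def argmax_label(p: np.ndarray, space: int = 5) -> str:
    """Predicted label for a probability vector; ties break by canonical order."""
    cats = categories(space)
    p = np.asarray(p, dtype=float)
    if p.shape != (space,):
        raise ValueError(f"expected shape ({space},), got {p.shape}")
    return cats[int(np.argmax(p))]
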