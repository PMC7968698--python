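"""In-memory dataset container for labelled trap sub-images.

A :class:`TrapDataset` couples an image stack ``(n, 60, 60)`` of
intensities in [0, 1] with a pandas manifest (one row per image: label,
split assignment, provenance).  Ground-truth per-cell masks from the
synthetic generator ride along when available so that geometric invariants
can be checked on the noise-free render.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .labels import CATEGORIES_5

TILE = 60  # side of a trap sub-image, pixels

SPLITS = ("train", "val", "test")


@dataclass
class TrapDataset:
    """Labelled 60x60 trap images with a manifest of labels and splits."""

    images: np.ndarray                      # (n, 60, 60) float64 in [0, 1]
    manifest: pd.DataFrame                  # columns: label5, split, ...
    masks: list[np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[1:] != (TILE, TILE):
            raise ValueError(
                f"images must be (n, {TILE}, {TILE}), got {self.images.shape}"
            )
        if len(self.manifest) != len(self.images):
            raise ValueError("manifest length does not match image count")
        bad = set(self.manifest["label5"]) - set(CATEGORIES_5)
        if bad:
            raise ValueError(f"unknown labels in manifest: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> list[str]:
        return list(self.manifest["label5"])

    def split(self, name: str) -> "TrapDataset":
        """The subset assigned to split ``name`` ('train'/'val'/'test')."""
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        idx = np.flatnonzero((self.manifest["split"] == name).to_numpy())
        return self.take(idx)

    def take(self, idx) -> "TrapDataset":
        idx = np.asarray(idx, dtype=int)
        masks = [self.masks[i] for i in idx] if self.masks is not None else None
        return TrapDataset(
            self.images[idx],
            self.manifest.iloc[idx].reset_index(drop=True),
            masks,
        )

    def save(self, out_dir: str | Path, with_masks: bool = False) -> Path:
        """Write 8-bit grayscale PNGs plus a ``manifest.csv`` under ``out_dir``.

        With ``with_masks=True`` the ground-truth cell masks (when present)
        are written alongside as label images (pixel value = cell index + 1).
        """
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        if with_masks and self.masks is not None:
            mask_dir = out_dir / "masks"
            mask_dir.mkdir(exist_ok=True)
        paths = []
        for i, img in enumerate(self.images):
            p = img_dir / f"img_{i:06d}.png"
            Image.fromarray(to_uint8(img), mode="L").save(p)
            paths.append(str(p.relative_to(out_dir)))
            if with_masks and self.masks is not None:
                lab = np.zeros((TILE, TILE), dtype=np.uint8)
                for k, m in enumerate(self.masks[i]):
                    lab[m] = k + 1
                Image.fromarray(lab, mode="L").save(mask_dir / f"mask_{i:06d}.png")
        man = self.manifest.copy()
        man.insert(0, "path", paths)
        man_path = out_dir / "manifest.csv"
        man.to_csv(man_path, index=False)
        return man_path


def to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)


def from_uint8(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=float) / 255.0


def onehot(labels: list[str], cats: tuple[str, ...]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(cats)}
    out = np.zeros((len(labels), len(cats)), dtype=np.float32)
    for r, lab in enumerate(labels):
        out[r, idx[lab]] = 1.0
    return out


def stratified_split(
    labels: list[str],
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign each item to train/val/test, stratified per category.

    Within every category the split counts differ from the exact proportion
    by at most one (largest-remainder apportionment); assignment within a
    category is a seeded shuffle.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must be nonnegative and sum to 1")
    labels_arr = np.asarray(labels)
    out = np.empty(len(labels_arr), dtype=object)
    for cat in sorted(set(labels_arr)):
        idx = np.flatnonzero(labels_arr == cat)
        rng.shuffle(idx)
        n = len(idx)
        exact = fractions * n
        counts = np.floor(exact).astype(int)
        rem = exact - counts
        for _ in range(n - counts.sum()):  # largest remainders get the leftovers
            k = int(np.argmax(rem))
            counts[k] += 1
            rem[k] = -1
        start = 0
        for split_name, c in zip(SPLITS, counts):
            out[idx[start : start + c]] = split_name
            start += c
    return out
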