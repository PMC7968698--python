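"""Image and manifest I/O, and partitioning of full frames into trap tiles.

A raw acquisition is a 1280x960 single-channel frame holding on the order
of a hundred traps; analysis operates on 60x60 sub-images, one per trap,
cut at externally supplied anchor coordinates (trap localization itself is
out of scope — anchors come from a CSV).  All intensities are normalized
to [0, 1] at load time: 8-bit images divide by 255, 16-bit by their dtype
maximum.  This module is the single entry point for that normalization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .data import TILE, TrapDataset, from_uint8, to_uint8
from .labels import CATEGORIES_5


@dataclass
class FramePartitionSpec:
    """Anchor-based partition of a frame into fixed-size tiles.

    Anchors are 0-based (row, col) coordinates of each tile's top-left
    corner, row-major convention.
    """

    frame_width: int = 1280
    frame_height: int = 960
    tile_size: int = TILE
    anchors: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        for i, (r, c) in enumerate(self.anchors):
            if not (0 <= r <= self.frame_height - self.tile_size):
                raise ValueError(
                    f"anchor {i} row {r} out of bounds for height "
                    f"{self.frame_height} and tile {self.tile_size}"
                )
            if not (0 <= c <= self.frame_width - self.tile_size):
                raise ValueError(
                    f"anchor {i} col {c} out of bounds for width "
                    f"{self.frame_width} and tile {self.tile_size}"
                )

    @staticmethod
    def from_csv(path: str | Path, frame_width=1280, frame_height=960,
                 tile_size=TILE) -> "FramePartitionSpec":
        """Read anchors from a two-column (row, col) CSV with header."""
        anchors = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                anchors.append((int(row["row"]), int(row["col"])))
        return FramePartitionSpec(frame_width, frame_height, tile_size, anchors)


def partition_frame(frame: np.ndarray, spec: FramePartitionSpec) -> np.ndarray:
    """Cut one tile per anchor out of ``frame``, in anchor order.

    Tiles are pure crops of the frame; returns ``(n_anchors, t, t)``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a single-channel 2-D image")
    if frame.shape != (spec.frame_height, spec.frame_width):
        raise ValueError(
            f"frame shape {frame.shape} does not match spec "
            f"({spec.frame_height}, {spec.frame_width})"
        )
    spec.validate()
    t = spec.tile_size
    return np.stack([frame[r : r + t, c : c + t] for r, c in spec.anchors]) \
        if spec.anchors else np.zeros((0, t, t), dtype=frame.dtype)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF as float intensities in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        img = Image.open(path)
        if img.mode not in ("L", "I", "I;16"):
            img = img.convert("L")
        arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype.kind in "ui":  # 16-bit acquisitions rescale by the dtype maximum
        return arr.astype(float) / float(np.iinfo(np.uint16).max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write [0, 1] intensities as an 8-bit grayscale PNG/TIFF."""
    path = Path(path)
    u8 = to_uint8(img)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u8)
    else:
        Image.fromarray(u8, mode="L").save(path)


def save_manifest(dataset: TrapDataset, out_dir: str | Path) -> Path:
    """Write the dataset's images and manifest CSV under ``out_dir``."""
    return dataset.save(out_dir)


def load_manifest(manifest_path: str | Path) -> TrapDataset:
    """Load a dataset from a ``manifest.csv`` written by :func:`save_manifest`.

    Rows must carry ``path`` and ``label5`` (and optionally ``split``);
    unknown labels and images that are not 60x60 are rejected with the
    offending row/path named.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(str(manifest_path))
    man = pd.read_csv(manifest_path)
    for col in ("path", "label5"):
        if col not in man.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    root = manifest_path.parent
    images = []
    for i, row in man.iterrows():
        if row["label5"] not in CATEGORIES_5:
            raise ValueError(f"manifest row {i}: unknown label {row['label5']!r}")
        img = read_image(root / row["path"])
        if img.shape != (TILE, TILE):
            raise ValueError(
                f"image {row['path']} has shape {img.shape}, expected "
                f"({TILE}, {TILE})"
            )
        images.append(img)
    if "split" not in man.columns:
        man["split"] = "train"
    keep = man.drop(columns=["path"])
    return TrapDataset(
        np.stack(images) if images else np.zeros((0, TILE, TILE)),
        keep.reset_index(drop=True),
    )


def load_split_directory(root: str | Path) -> dict[str, dict[str, int]]:
    """Count images in a ``<root>/<split>/<category>/*.png`` directory tree.

    This is the layout of the published trap-image dataset release (train /
    validation / test folders with one subfolder per computed category;
    the published release holds 3,078 training, 1,026 validation and 896
    test images).  Returns ``{split: {category: count}}`` including a
    ``total`` entry per split; unknown category folders are rejected.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(str(root))
    aliases = {"train": "train", "training": "train", "val": "val",
               "validation": "val", "test": "test", "testing": "test"}
    report: dict[str, dict[str, int]] = {}
    for sub in sorted(root.iterdir()):
        if not sub.is_dir() or sub.name.lower() not in aliases:
            continue
        split = aliases[sub.name.lower()]
        counts: dict[str, int] = {}
        for catdir in sorted(sub.iterdir()):
            if not catdir.is_dir():
                continue
            if catdir.name not in CATEGORIES_5:
                raise ValueError(
                    f"unknown category folder {catdir.name!r} under {sub}"
                )
            counts[catdir.name] = sum(
                1 for p in catdir.iterdir()
                if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg")
            )
        counts["total"] = sum(counts.values())
        report[split] = counts
    if not report:
        raise ValueError(f"no train/val/test split folders found under {root}")
    return report
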