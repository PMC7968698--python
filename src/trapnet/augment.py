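"""Seeded affine and photometric augmentation of training images.

Manual annotation keeps real trap datasets small, so training relies on
label-preserving transforms: rotation, width/height shifts, brightness
scaling, horizontal/vertical flips and additive Gaussian noise, plus
optional feature-wise centering / std normalization fitted on the training
split only.  Augmentation applies to the training split exclusively —
validation and test images are never transformed — and a ``multiplier``
controls how many augmented variants each source image yields.

Geometric transforms fill exposed borders by edge replication so no
artificial dark corners are introduced.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .data import TrapDataset


@dataclass(frozen=True)
class AugmentationConfig:
    """Transform magnitudes; all ranges are symmetric around identity.

    ``rotation_range`` is in degrees, shifts are fractions of the 60 px
    tile, ``brightness_range`` is a multiplicative interval, and
    ``noise_sigma`` is additive on [0, 1] intensities.
    """

    # magnitudes are kept gentle: cells span only ~8-18 px of the 60 px
    # tile, so larger rotations/shifts push degraded scenes beyond what
    # small models can fit within a short epoch budget
    rotation_range: float = 8.0
    width_shift: float = 0.05
    height_shift: float = 0.05
    brightness_range: tuple[float, float] = (0.9, 1.1)
    horizontal_flip: bool = True
    # a vertical flip moves a daughter from above to below the mother (and
    # vice versa), so it does NOT preserve the two orientation labels;
    # off by default, enable only for orientation-free category subsets
    vertical_flip: bool = False
    noise_sigma: float = 0.01
    featurewise_center: bool = False
    featurewise_std_normalization: bool = False
    multiplier: int = 32

    def __post_init__(self):
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.rotation_range < 0 or self.width_shift < 0 or self.height_shift < 0:
            raise ValueError("transform ranges must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        lo, hi = self.brightness_range
        if lo > hi or lo < 0:
            raise ValueError("brightness_range must be 0 <= low <= high")

    @staticmethod
    def identity(multiplier: int = 1) -> "AugmentationConfig":
        """A configuration under which every output equals its source."""
        return AugmentationConfig(
            rotation_range=0.0, width_shift=0.0, height_shift=0.0,
            brightness_range=(1.0, 1.0), horizontal_flip=False,
            vertical_flip=False, noise_sigma=0.0, multiplier=multiplier,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @staticmethod
    def from_yaml(path: str | Path) -> "AugmentationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if isinstance(raw.get("brightness_range"), list):
            raw["brightness_range"] = tuple(raw["brightness_range"])
        return AugmentationConfig(**raw)


def transform_image(img: np.ndarray, cfg: AugmentationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Apply one random draw of the configured transforms to ``img``."""
    out = img
    if cfg.rotation_range > 0:
        ang = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
        out = ndimage.rotate(out, ang, reshape=False, order=1, mode="nearest")
    if cfg.width_shift > 0 or cfg.height_shift > 0:
        dy = rng.uniform(-cfg.height_shift, cfg.height_shift) * img.shape[0]
        dx = rng.uniform(-cfg.width_shift, cfg.width_shift) * img.shape[1]
        out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
    if cfg.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        out = out[::-1, :]
    lo, hi = cfg.brightness_range
    if not (lo == hi == 1.0):
        out = out * rng.uniform(lo, hi)
    if cfg.noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.noise_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


def augment_dataset(train: TrapDataset, cfg: AugmentationConfig,
                    seed: int = 0) -> TrapDataset:
    """Produce ``cfg.multiplier`` seeded augmented variants per source image.

    Labels carry over unchanged; the output manifest records each variant's
    source row in ``source_index``.  Identical (inputs, cfg, seed) produce
    identical outputs.
    """
    if np.any(train.manifest.get("split", "train") == "val") or np.any(
        train.manifest.get("split", "train") == "test"
    ):
        raise ValueError("augmentation applies to the training split only")
    rng = np.random.default_rng(seed)
    images, labels, sources = [], [], []
    for i, img in enumerate(train.images):
        for _ in range(cfg.multiplier):
            images.append(transform_image(img, cfg, rng))
            labels.append(train.manifest["label5"].iloc[i])
            sources.append(i)
    manifest = pd.DataFrame(
        {"label5": labels, "split": "train", "source_index": sources}
    )
    return TrapDataset(np.stack(images), manifest)


@dataclass
class FeatureStats:
    """Per-pixel mean/std images fitted on the training split."""

    mean: np.ndarray
    std: np.ndarray
    fitted: bool = True


def fit_feature_stats(train: TrapDataset | np.ndarray) -> FeatureStats:
    """Fit the per-pixel mean and std on training images only."""
    images = train.images if isinstance(train, TrapDataset) else np.asarray(train)
    if len(images) == 0:
        raise ValueError("cannot fit feature statistics on an empty set")
    return FeatureStats(mean=images.mean(axis=0), std=images.std(axis=0))


def apply_feature_norm(images: np.ndarray, stats: FeatureStats) -> np.ndarray:
    """Center (and, where std > 0, scale) images by the fitted statistics."""
    if not isinstance(stats, FeatureStats) or not stats.fitted:
        raise ValueError("feature statistics must be fitted before applying")
    out = np.asarray(images, dtype=float) - stats.mean
    safe = np.where(stats.std > 0, stats.std, 1.0)
    return out / safe
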