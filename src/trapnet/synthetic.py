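"""Synthetic generator of labelled microfluidic trap sub-images.

Emulates the geometry and nuisance structure of bright-field time-lapse
images of a yeast-aging microfluidic chip: each 60x60 tile shows one trap —
a pocket with a wider inlet at the top and a narrower outlet at the bottom
that retains the large mother cell while daughters slip out with the medium
flow — plus zero or more cells rendered as dark-rimmed, lighter-bodied
ellipses.  Nuisance variation mimics what makes the real tiles hard:
Gaussian blur, background brightness shifts, one-sided shadows, additive
sensor noise, and occasional near-transparent (senescent-looking) cells.

Five scene categories are generated:

======  ====================================================
label   scene contents
======  ====================================================
nC      empty trap
mC      a single mother cell at the trap centre
mduC    mother + one daughter strictly above it
mddC    mother + one daughter strictly below it
exC     mother + at least two additional cells (crowded)
======  ====================================================

Cell interiors never overlap in the ground-truth masks, so a connected-
component count of the pre-noise mask always equals the number of rendered
cells; masks are retained on the dataset for exactly that kind of check.
All randomness flows through ``numpy.random.Generator`` seeded per scene,
so identical (label, params, seed) triples render identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .data import TILE, TrapDataset, stratified_split
from .labels import CATEGORIES_5

import pandas as pd

#: Device-to-image scale.  The trap inlet/outlet are 6 and 3 micrometres
#: wide; at 6 px/um the trap occupies the central ~2/3 of the 60 px tile.
PX_PER_UM = 6.0


@dataclass(frozen=True)
class SceneParams:
    """Geometry and nuisance parameters of the synthetic scene.

    All lengths are pixels on the 60x60 tile, all intensities lie in [0, 1].
    ``daughter_radius_range[1]`` must stay strictly below
    ``mother_radius_range[0]`` so mothers and daughters are unambiguous.
    ``daughter_offset_factor`` scales the mother-daughter centre distance in
    units of the summed radii; values just above 1 render touching cells.
    """

    trap_inlet_width: float = 6.0 * PX_PER_UM
    trap_outlet_width: float = 3.0 * PX_PER_UM
    mother_radius_range: tuple[float, float] = (7.0, 9.0)
    daughter_radius_range: tuple[float, float] = (3.5, 5.0)
    extra_cell_count_range: tuple[int, int] = (2, 4)
    blur_sigma_range: tuple[float, float] = (0.4, 0.8)
    background_level_range: tuple[float, float] = (0.55, 0.70)
    noise_sigma: float = 0.02
    shadow_probability: float = 0.2
    transparent_cell_probability: float = 0.02
    daughter_offset_factor: float = 1.25
    rim_contrast: float = 0.35
    interior_contrast: float = 0.10

    def __post_init__(self):
        for name in ("mother_radius_range", "daughter_radius_range",
                     "extra_cell_count_range", "blur_sigma_range",
                     "background_level_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has low > high: ({lo}, {hi})")
        if self.daughter_radius_range[1] >= self.mother_radius_range[0]:
            raise ValueError(
                "daughter radius upper bound must be strictly below the "
                "mother radius lower bound"
            )
        for name in ("noise_sigma", "shadow_probability",
                     "transparent_cell_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.background_level_range
        if not (0.0 <= lo and hi <= 1.0):
            raise ValueError("background levels must lie in [0, 1]")
        if self.extra_cell_count_range[0] < 2:
            raise ValueError("exC requires at least 2 extra cells")

    @staticmethod
    def easy() -> "SceneParams":
        """Clean, well-separated scenes: classifiers should be near-perfect."""
        return SceneParams()

    @staticmethod
    def hard() -> "SceneParams":
        """Near-touching cells, stronger blur/noise/shadows and frequent
        near-transparent cells: calibrated so classifiers sit clearly
        below ceiling but above chance, keeping model comparisons
        informative."""
        return SceneParams(
            mother_radius_range=(6.0, 9.0),
            daughter_radius_range=(3.0, 5.5),
            blur_sigma_range=(0.7, 1.3),
            background_level_range=(0.45, 0.75),
            noise_sigma=0.05,
            shadow_probability=0.4,
            transparent_cell_probability=0.10,
            daughter_offset_factor=1.05,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @staticmethod
    def from_yaml(path: str | Path) -> "SceneParams":
        raw = yaml.safe_load(Path(path).read_text())
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return SceneParams(**raw)


@dataclass
class LabeledImage:
    """A rendered scene: image, label, per-cell ground-truth masks."""

    image: np.ndarray                 # (60, 60) float in [0, 1]
    label: str
    cell_masks: np.ndarray            # (n_cells, 60, 60) bool, pre-noise
    provenance: dict


# -- rendering ---------------------------------------------------------------

_YY, _XX = np.mgrid[0:TILE, 0:TILE].astype(float)


def _draw_trap(img: np.ndarray, params: SceneParams, rng: np.random.Generator) -> None:
    """Two dark walls converging from the inlet width at the top of the trap
    to the outlet width at the bottom, anti-aliased."""
    top, bottom = 10.0, 50.0
    cx = TILE / 2 + rng.uniform(-1.0, 1.0)
    t = np.clip((_YY - top) / (bottom - top), 0.0, 1.0)
    half = (params.trap_inlet_width + t * (params.trap_outlet_width - params.trap_inlet_width)) / 2.0
    in_band = (_YY >= top) & (_YY <= bottom)
    wall_w = 1.6
    for side in (-1.0, 1.0):
        dist = np.abs((_XX - cx) - side * half)
        alpha = np.clip(1.0 - dist / wall_w, 0.0, 1.0) * in_band
        img -= 0.30 * alpha
    # short inlet lips flaring outward at the top
    lip = (np.abs(_YY - top) < 1.5) & (np.abs(_XX - cx) > half) & (
        np.abs(_XX - cx) < half + 6.0
    )
    img[lip] -= 0.18


def _draw_cell(
    img: np.ndarray,
    center: tuple[float, float],
    radii: tuple[float, float],
    params: SceneParams,
    transparent: bool,
) -> np.ndarray:
    """Anti-aliased ellipse with a dark rim and lighter interior (bright-field
    appearance).  Returns the boolean interior mask."""
    cy, cx = center
    ry, rx = radii
    d = np.sqrt(((_YY - cy) / ry) ** 2 + ((_XX - cx) / rx) ** 2)
    rim_w = 1.2 / min(ry, rx)
    fade = 0.3 if transparent else 1.0
    rim = np.clip(1.0 - np.abs(d - 1.0) / rim_w, 0.0, 1.0)
    interior = np.clip(1.0 - d / (1.0 - rim_w), 0.0, 1.0)
    img -= params.rim_contrast * fade * rim
    img += params.interior_contrast * fade * np.clip(interior, 0, 1)
    return d < 1.0


def _place_cells(label: str, params: SceneParams, rng: np.random.Generator):
    """Choose cell centres/radii for the label; interiors never overlap."""
    cells: list[tuple[tuple[float, float], tuple[float, float]]] = []
    if label == "nC":
        return cells
    rm = rng.uniform(*params.mother_radius_range)
    mc = (TILE / 2 + rng.uniform(-2.0, 2.0), TILE / 2 + rng.uniform(-1.5, 1.5))
    cells.append((mc, (rm, rm * rng.uniform(0.9, 1.0))))
    if label == "mC":
        return cells
    if label in ("mduC", "mddC"):
        rd = rng.uniform(*params.daughter_radius_range)
        sign = -1.0 if label == "mduC" else 1.0
        # +2 px keeps a clear pixel gap between the rasterized interiors
        dy = sign * ((rm + rd) * params.daughter_offset_factor + 2.0)
        dx = rng.uniform(-2.0, 2.0)
        dc = (float(np.clip(mc[0] + dy, rd + 1, TILE - rd - 1)), mc[1] + dx)
        cells.append((dc, (rd, rd * rng.uniform(0.9, 1.0))))
        return cells
    # exC: mother plus >=2 extra cells, rejection-placed to keep interiors apart
    n_extra = int(rng.integers(params.extra_cell_count_range[0],
                               params.extra_cell_count_range[1] + 1))
    placed = 0
    attempts = 0
    while placed < n_extra and attempts < 400:
        attempts += 1
        re = rng.uniform(*params.daughter_radius_range)
        ang = rng.uniform(0, 2 * np.pi)
        dist = (rm + re) * rng.uniform(1.05, 1.6) + 2.0
        c = (mc[0] + dist * np.sin(ang), mc[1] + dist * np.cos(ang))
        if not (re + 1 <= c[0] <= TILE - re - 1 and re + 1 <= c[1] <= TILE - re - 1):
            continue
        ok = all(
            np.hypot(c[0] - oc[0], c[1] - oc[1]) >= (re + orr[0]) * 1.05 + 2.0
            for oc, orr in cells
        )
        if ok:
            cells.append((c, (re, re * rng.uniform(0.9, 1.0))))
            placed += 1
    if placed < 2:
        raise RuntimeError("could not place the extra cells for an exC scene")
    return cells


def generate_scene(label: str, params: SceneParams, seed: int) -> LabeledImage:
    """Render one labelled 60x60 trap scene deterministically from ``seed``."""
    if label not in CATEGORIES_5:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    bg = rng.uniform(*params.background_level_range)
    img = np.full((TILE, TILE), bg)
    _draw_trap(img, params, rng)
    cells = _place_cells(label, params, rng)
    masks = []
    for center, radii in cells:
        transparent = rng.random() < params.transparent_cell_probability
        masks.append(_draw_cell(img, center, radii, params, transparent))
    # nuisance: one-sided multiplicative shadow, blur, additive noise
    if rng.random() < params.shadow_probability:
        ang = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(ang) * (_XX / TILE - 0.5) + np.sin(ang) * (_YY / TILE - 0.5))
        img *= 1.0 - rng.uniform(0.1, 0.35) * (ramp + 0.5)
    sigma = rng.uniform(*params.blur_sigma_range)
    img = ndimage.gaussian_filter(img, sigma)
    img += rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    cell_masks = (
        np.stack(masks) if masks else np.zeros((0, TILE, TILE), dtype=bool)
    )
    return LabeledImage(
        image=img,
        label=label,
        cell_masks=cell_masks,
        provenance={"seed": int(seed), "label": label},
    )


def generate_dataset(
    per_class_counts: dict[str, int],
    params: SceneParams | None = None,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> TrapDataset:
    """Generate a labelled dataset with disjoint, stratified splits.

    ``per_class_counts`` maps each category to the number of scenes to
    render (omitted categories get zero).  Scene seeds derive from ``seed``
    and the draw index, so the whole dataset is reproducible bit-for-bit.
    """
    params = params or SceneParams()
    unknown = set(per_class_counts) - set(CATEGORIES_5)
    if unknown:
        raise ValueError(f"unknown labels in counts: {sorted(unknown)}")
    if any(v < 0 for v in per_class_counts.values()):
        raise ValueError("per-class counts must be nonnegative")
    images, labels, masks, seeds = [], [], [], []
    draw = 0
    for cat in CATEGORIES_5:
        for _ in range(per_class_counts.get(cat, 0)):
            scene_seed = (seed * 1_000_003 + draw) % (2**31)
            scene = generate_scene(cat, params, scene_seed)
            images.append(scene.image)
            labels.append(cat)
            masks.append(scene.cell_masks)
            seeds.append(scene_seed)
            draw += 1
    rng = np.random.default_rng(seed)
    split = stratified_split(labels, split_fractions, rng)
    manifest = pd.DataFrame(
        {"label5": labels, "split": split, "scene_seed": seeds}
    )
    images_arr = (
        np.stack(images) if images else np.zeros((0, TILE, TILE))
    )
    return TrapDataset(images_arr, manifest, masks)
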