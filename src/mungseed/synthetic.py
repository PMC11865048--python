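"""Synthetic mung-bean seed photographs with ground truth.

Emulates the acquisition setup the pipeline was designed for: bright,
ellipsoidal seeds laid out on a grid over a near-black absorbent cloth,
photographed from above, one variety per image. Each variety (class) gets its
own hue/size/brightness/texture distribution so that (a) a fixed 0.4
gray-level threshold separates seeds from background and (b) the classes are
statistically separable — which is what makes the downstream segmentation,
augmentation and training stages testable without the original photographs.

Rendering is deliberately simple: filled ellipses with a ~1 px anti-aliased
rim and additive per-pixel texture noise. No camera optics, shadows or
specular highlights are modelled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image

__all__ = [
    "ClassAppearance",
    "SyntheticSceneSpec",
    "default_appearances",
    "generate_scene",
    "generate_dataset",
    "CapacityError",
]

SEGMENTATION_THRESHOLD = 0.4  # gray level separating seeds from cloth


class CapacityError(ValueError):
    """More seeds requested than grid positions available."""


@dataclass(frozen=True)
class ClassAppearance:
    """Per-variety appearance distribution."""

    hue_mean: float            # [0, 1) colour-wheel position
    hue_sd: float = 0.02
    axes_mean: tuple[float, float] = (60.0, 48.0)  # ellipse semi-axes, px
    axes_sd: float = 4.0
    brightness_mean: float = 0.75   # HSV value; must stay above the threshold
    saturation: float = 0.18
    texture_noise: float = 0.02     # additive per-pixel noise amplitude


def default_appearances(n_classes: int, image_size: int = 224) -> tuple[ClassAppearance, ...]:
    """Evenly spaced hues, mildly varying size/brightness across classes.

    Saturation is kept low (dry seeds are desaturated) which also guarantees
    the gray-level luma of every seed pixel stays well above 0.4 for any hue.
    """
    scale = image_size / 224.0
    out = []
    for i in range(n_classes):
        out.append(ClassAppearance(
            hue_mean=(0.06 + i / n_classes) % 1.0,
            axes_mean=((60 + 4 * (i % 3)) * scale, (46 + 3 * (i % 4)) * scale),
            axes_sd=4.0 * scale,
            brightness_mean=0.68 + 0.03 * (i % 5),
            saturation=0.12 + 0.02 * (i % 4),
        ))
    return tuple(out)


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of a generated seed photograph."""

    image_size: tuple[int, int] = (224, 224)   # (H, W)
    grid: tuple[int, int] = (1, 1)             # (rows, cols) of seed positions
    background_level: float = 0.05             # cloth gray value
    n_classes: int = 8
    class_appearance: tuple[ClassAppearance, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.background_level <= 0.2:
            raise ValueError("background_level must lie in [0, 0.2]")
        if self.background_level >= SEGMENTATION_THRESHOLD:
            raise ValueError("background must stay below the 0.4 threshold")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        appearance = self.class_appearance or default_appearances(
            self.n_classes, min(self.image_size))
        if len(appearance) != self.n_classes:
            raise ValueError("one appearance record per class required")
        for app in appearance:
            if app.brightness_mean <= SEGMENTATION_THRESHOLD:
                raise ValueError(
                    "seed brightness means must exceed the 0.4 threshold")
        object.__setattr__(self, "class_appearance", tuple(appearance))

    @property
    def capacity(self) -> int:
        return self.grid[0] * self.grid[1]


def _render_seed(image, mask, app: ClassAppearance, cell, rng):
    """Draw one anti-aliased ellipse confined to ``cell``; returns its bbox.

    The ellipse (semi-axes capped to the cell) is centred with a uniform
    jitter small enough that it never leaves the cell, so seeds in distinct
    cells have disjoint bounding boxes by construction.
    """
    h, w = mask.shape
    top, left, bottom, right = cell
    max_semi = 0.5 * min(bottom - top, right - left) - 2.0
    a = float(np.clip(rng.normal(app.axes_mean[0], app.axes_sd), 4.0, max_semi))
    b = float(np.clip(rng.normal(app.axes_mean[1], app.axes_sd), 3.0, max_semi))
    theta = rng.uniform(0, np.pi)
    rmax = max(a, b)
    my = max(0.0, 0.5 * (bottom - top) - rmax - 1.5)
    mx = max(0.0, 0.5 * (right - left) - rmax - 1.5)
    cy = 0.5 * (top + bottom) + rng.uniform(-my, my)
    cx = 0.5 * (left + right) + rng.uniform(-mx, mx)
    rad = max(a, b) + 1.5
    r0, r1 = int(max(0, np.floor(cy - rad))), int(min(h, np.ceil(cy + rad) + 1))
    c0, c1 = int(max(0, np.floor(cx - rad))), int(min(w, np.ceil(cx + rad) + 1))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    dist = np.sqrt(u * u + v * v)
    edge = 1.0 / max(a, b)  # ~1 px smooth rim
    alpha = np.clip((1.0 - dist) / edge, 0.0, 1.0)

    hue = rng.normal(app.hue_mean, app.hue_sd) % 1.0
    value = float(np.clip(rng.normal(app.brightness_mean, 0.02), 0.55, 0.98))
    base = hsv_to_rgb([hue, app.saturation, value])
    patch = np.empty(alpha.shape + (3,))
    patch[:] = base
    if app.texture_noise > 0:
        patch += rng.normal(0.0, app.texture_noise, patch.shape)
    patch = np.clip(patch, 0.0, 1.0)

    region = image[r0:r1, c0:c1]
    image[r0:r1, c0:c1] = region * (1 - alpha[..., None]) + patch * alpha[..., None]
    inside = alpha >= 0.5
    mask[r0:r1, c0:c1] |= inside
    rows, cols = np.nonzero(inside)
    return (r0 + rows.min(), c0 + cols.min(), r0 + rows.max() + 1, c0 + cols.max() + 1)


def generate_scene(spec: SyntheticSceneSpec, class_label: int, n_seeds: int,
                   seed: int):
    """Render one photograph of ``n_seeds`` same-variety seeds.

    Returns ``(rgb, mask, bboxes)``: an (H, W, 3) float image in [0, 1], the
    (H, W) binary ground-truth mask and one (r0, c0, r1, c1) box per seed.
    Seeds occupy distinct grid cells, so their boxes are pairwise disjoint.
    Deterministic for a given ``seed``.
    """
    if n_seeds < 0:
        raise ValueError("n_seeds must be non-negative")
    if n_seeds > spec.capacity:
        raise CapacityError(
            f"{n_seeds} seeds exceed the {spec.grid[0]}x{spec.grid[1]} grid capacity")
    if not 0 <= class_label < spec.n_classes:
        raise ValueError(f"class_label {class_label} out of range")
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    image = np.full((h, w, 3), spec.background_level)
    image += rng.normal(0.0, 0.01, image.shape)
    image = np.clip(image, 0.0, 0.2)
    mask = np.zeros((h, w), dtype=bool)
    app = spec.class_appearance[class_label]

    rows, cols = spec.grid
    cell_h, cell_w = h / rows, w / cols
    cells = rng.permutation(rows * cols)[:n_seeds]
    bboxes = []
    for cell in cells:
        r, c = divmod(int(cell), cols)
        rect = (r * cell_h, c * cell_w, (r + 1) * cell_h, (c + 1) * cell_w)
        bboxes.append(_render_seed(image, mask, app, rect, rng))
    return image, mask.astype(np.uint8), bboxes


def _sub_seed(base_seed: int, index: int) -> int:
    """Counter scheme fanning one dataset seed out to per-image seeds."""
    return (base_seed * 1_000_003 + index) % (2 ** 31)


def generate_dataset(spec: SyntheticSceneSpec, counts_per_class,
                     out_dir, seed: int, class_names=None) -> pd.DataFrame:
    """Write single-seed crops to ``out_dir/<class>/<index>.png``.

    Each crop is a one-seed scene at ``spec.image_size``. Returns the manifest
    (columns ``path, label, split, origin``) with one row per written file;
    the same frame is saved as ``out_dir/manifest.csv``.
    """
    counts = [int(c) for c in counts_per_class]
    if len(counts) != spec.n_classes:
        raise ValueError("one count per class required")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if class_names is None:
        class_names = [f"class_{i}" for i in range(spec.n_classes)]
    out_dir = Path(out_dir)
    crop_spec = replace(spec, grid=(1, 1))
    rows = []
    index = 0
    for label, (name, count) in enumerate(zip(class_names, counts)):
        cls_dir = out_dir / name
        if count:
            cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            rgb, _, _ = generate_scene(crop_spec, label, 1, _sub_seed(seed, index))
            path = cls_dir / f"{i:05d}.png"
            save_image(rgb, path)
            rows.append({"path": str(path), "label": name,
                         "split": "", "origin": "original"})
            index += 1
    manifest = pd.DataFrame(rows, columns=["path", "label", "split", "origin"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def save_image(rgb: np.ndarray, path) -> None:
    """Save a float [0,1] (or uint8) RGB array as PNG."""
    if rgb.dtype != np.uint8:
        rgb = (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    """Load an image file as float RGB in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
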