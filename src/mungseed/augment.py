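"""Offline data enhancement and the 8:1:1 stratified split.

Four fixed operators expand every source image five-fold: doubled
brightness, additive Gaussian noise (mean 1, sd 1.5 on the 0-255 intensity
scale — a deliberately tiny perturbation), mirroring and rotation. The split
rule is exact integer arithmetic per class: train = floor(0.8 N),
val = floor(0.1 N), test takes the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance

__all__ = [
    "AugmentConfig",
    "SplitRatios",
    "brighten",
    "add_gaussian_noise",
    "mirror",
    "rotate",
    "enhance_manifest",
    "enhance_dataset",
    "split_counts",
    "split_dataset",
    "ENHANCEMENT_OPS",
]

ENHANCEMENT_OPS = ("original", "brightness", "noise", "mirror", "rotation")


@dataclass(frozen=True)
class AugmentConfig:
    brightness_factor: float = 2.0
    noise_mean: float = 1.0       # 0-255 intensity units
    noise_sd: float = 1.5
    mirror_axis: str = "horizontal"
    rotation_angle: float = 90.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.brightness_factor <= 0:
            raise ValueError("brightness_factor must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mirror_axis not in ("horizontal", "vertical"):
            raise ValueError("mirror_axis must be 'horizontal' or 'vertical'")


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.8
    val: float = 0.1
    test: float = 0.1

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("split ratios must be non-negative")


def _as_uint8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image
    return (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def brighten(image: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Per-pixel brightness multiplication (clipped), uint8 in/out."""
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    im = Image.fromarray(_as_uint8(image))
    return np.asarray(ImageEnhance.Brightness(im).enhance(factor))


def add_gaussian_noise(image: np.ndarray, mean: float = 1.0, sd: float = 1.5,
                       seed: int = 0) -> np.ndarray:
    """Add N(mean, sd^2) noise per pixel on the 0-255 scale, clip to [0, 255]."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    img = _as_uint8(image).astype(np.float64)
    noise = np.random.default_rng(seed).normal(mean, sd, img.shape)
    return np.clip(img + noise, 0.0, 255.0).round().astype(np.uint8)


def mirror(image: np.ndarray, axis: str = "horizontal") -> np.ndarray:
    """Mirror the image; an involution. 'horizontal' flips left-right."""
    image = np.asarray(image)
    if axis == "horizontal":
        return image[:, ::-1].copy()
    if axis == "vertical":
        return image[::-1].copy()
    raise ValueError("axis must be 'horizontal' or 'vertical'")


def rotate(image: np.ndarray, angle: float = 90.0) -> np.ndarray:
    """Rotate counter-clockwise on the same canvas.

    Multiples of 90 degrees on square images are exact (pure index
    permutation); other angles go through bilinear resampling with black
    fill.
    """
    image = np.asarray(image)
    angle = float(angle) % 360.0
    if angle == 0.0:
        return image.copy()
    h, w = image.shape[:2]
    if angle % 90.0 == 0.0 and h == w:
        return np.rot90(image, k=int(angle // 90)).copy()
    im = Image.fromarray(_as_uint8(image))
    return np.asarray(im.rotate(angle, resample=Image.BILINEAR, expand=False))


def enhance_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Pure five-fold row expansion with provenance tags (no file I/O).

    Useful for dataset arithmetic: |output| = 5 |input| always, with the
    ``origin`` column recording which operator each row stands for.
    """
    frames = []
    for op in ENHANCEMENT_OPS:
        part = manifest.copy()
        part["origin"] = op
        if op != "original":
            part["path"] = [_variant_name(p, op) for p in part["path"]]
        frames.append(part)
    return pd.concat(frames, ignore_index=True)


def _variant_name(path: str, op: str) -> str:
    p = Path(path)
    return str(p.with_name(f"{p.stem}_{op}{p.suffix}"))


def enhance_dataset(manifest: pd.DataFrame, out_dir,
                    config: AugmentConfig = AugmentConfig()) -> pd.DataFrame:
    """Materialise the five-fold enhancement under ``out_dir/<label>/``.

    Every source image is copied and its four variants written; the returned
    manifest has exactly 5x the input rows. Missing source files raise a
    FileNotFoundError naming them.
    """
    out_dir = Path(out_dir)
    missing = [p for p in manifest["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing source images: {missing[:5]}"
                                + (" ..." if len(missing) > 5 else ""))
    rows = []
    for i, rec in enumerate(manifest.itertuples(index=False)):
        with Image.open(rec.path) as im:
            src = np.asarray(im.convert("RGB"))
        dest = out_dir / str(rec.label)
        dest.mkdir(parents=True, exist_ok=True)
        stem = Path(rec.path).stem
        variants = {
            "original": src,
            "brightness": brighten(src, config.brightness_factor),
            "noise": add_gaussian_noise(src, config.noise_mean, config.noise_sd,
                                        seed=(config.rng_seed * 1_000_003 + i) % (2 ** 31)),
            "mirror": mirror(src, config.mirror_axis),
            "rotation": rotate(src, config.rotation_angle),
        }
        for op in ENHANCEMENT_OPS:
            name = f"{stem}.png" if op == "original" else f"{stem}_{op}.png"
            path = dest / name
            Image.fromarray(variants[op]).save(path)
            rows.append({"path": str(path), "label": rec.label,
                         "split": "", "origin": op})
    enhanced = pd.DataFrame(rows, columns=["path", "label", "split", "origin"])
    out_dir.mkdir(parents=True, exist_ok=True)
    enhanced.to_csv(out_dir / "manifest.csv", index=False)
    return enhanced


def split_counts(n: int, ratios: SplitRatios = SplitRatios()) -> tuple[int, int, int]:
    """Integer per-class split sizes: floor train, floor val, remainder test."""
    train = int(n * ratios.train + 1e-9)
    val = int(n * ratios.val + 1e-9)
    test = n - train - val
    return train, val, test


def split_dataset(manifest: pd.DataFrame, ratios: SplitRatios = SplitRatios(),
                  seed: int = 0, group_by_source: bool = False):
    """Random stratified split into (train, val, test) manifests.

    Shuffles within each class and assigns by :func:`split_counts`. With
    ``group_by_source`` the five enhancement variants of one source image are
    kept in the same split (leak-free evaluation); the default splits rows
    independently, matching an enhancement-then-split protocol.
    """
    rng = np.random.default_rng(seed)
    parts = {"train": [], "val": [], "test": []}
    for _, group in manifest.groupby("label", sort=True):
        if group_by_source:
            stems = group["path"].map(_source_stem)
            uniq = pd.unique(stems)
            order = rng.permutation(len(uniq))
            n_tr, n_va, _ = split_counts(len(uniq), ratios)
            assign = {}
            for rank, j in enumerate(order):
                assign[uniq[j]] = ("train" if rank < n_tr
                                   else "val" if rank < n_tr + n_va else "test")
            for split_name in parts:
                sel = group[stems.map(assign) == split_name]
                parts[split_name].append(sel)
        else:
            order = rng.permutation(len(group))
            n_tr, n_va, _ = split_counts(len(group), ratios)
            shuffled = group.iloc[order]
            parts["train"].append(shuffled.iloc[:n_tr])
            parts["val"].append(shuffled.iloc[n_tr:n_tr + n_va])
            parts["test"].append(shuffled.iloc[n_tr + n_va:])
    out = []
    for name in ("train", "val", "test"):
        df = (pd.concat(parts[name], ignore_index=True) if parts[name]
              else manifest.iloc[0:0].copy())
        df = df.assign(split=name)
        out.append(df)
    return tuple(out)


def _source_stem(path: str) -> str:
    stem = Path(path).stem
    for op in ENHANCEMENT_OPS[1:]:
        suffix = f"_{op}"
        if stem.endswith(suffix):
            return stem[: -len(suffix)]
    return stem
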