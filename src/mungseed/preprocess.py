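"""Threshold segmentation and per-seed cropping.

The pipeline: grayscale conversion, fixed-threshold binarisation (default
0.4 — the background cloth sits near black, seeds well above), pixel-wise
masking of the original image, connected-region extraction and padded
bounding-box crops resized to the model input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure, transform

from .synthetic import load_image, save_image

__all__ = [
    "PreprocessConfig",
    "to_grayscale",
    "binarize",
    "apply_mask",
    "extract_seed_crops",
    "segment_image",
    "preprocess_directory",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocessConfig:
    threshold: float = 0.4
    min_region_area: int = 50      # px; rejects speckle
    crop_padding: int = 4          # px around each region's bounding box
    output_size: int = 224         # square crop side after resize
    blur_variance_min: float | None = None  # optional blur filter, off by default

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma (0.299 R + 0.587 G + 0.114 B) of a [0,1] RGB image."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {rgb.shape}")
    return rgb @ _LUMA


def binarize(gray: np.ndarray, threshold: float = 0.4) -> np.ndarray:
    """Fixed-threshold binary mask: pixel >= threshold -> 1, else 0.

    Equality maps to 1 (the published rule only fixes the strict cases).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected an (H, W) gray image, got shape {gray.shape}")
    return (gray >= threshold).astype(np.uint8)


def apply_mask(rgb: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixel-wise product: keep the image where mask=1, black elsewhere."""
    rgb = np.asarray(rgb, dtype=np.float64)
    mask = np.asarray(mask)
    if rgb.shape[:2] != mask.shape:
        raise ValueError(f"image {rgb.shape[:2]} and mask {mask.shape} disagree")
    return rgb * mask[..., None]


def _blur_variance(gray_crop: np.ndarray) -> float:
    """Variance of a 3x3 Laplacian response — a standard sharpness score."""
    lap = (-4 * gray_crop[1:-1, 1:-1] + gray_crop[:-2, 1:-1] + gray_crop[2:, 1:-1]
           + gray_crop[1:-1, :-2] + gray_crop[1:-1, 2:])
    return float(lap.var())


def extract_seed_crops(masked: np.ndarray, mask: np.ndarray,
                       config: PreprocessConfig = PreprocessConfig()) -> list[np.ndarray]:
    """One resized crop per connected region of sufficient area.

    Regions are 8-connected components of the mask; each surviving region's
    bounding box is padded by ``crop_padding`` (clipped at the frame) and
    resized bilinearly to ``output_size`` squared. An empty mask yields an
    empty list.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    labels = measure.label(mask, connectivity=2)
    crops = []
    h, w = mask.shape
    pad = config.crop_padding
    for region in measure.regionprops(labels):
        if region.area < config.min_region_area:
            continue
        r0, c0, r1, c1 = region.bbox
        r0, c0 = max(0, r0 - pad), max(0, c0 - pad)
        r1, c1 = min(h, r1 + pad), min(w, c1 + pad)
        crop = masked[r0:r1, c0:c1]
        if config.blur_variance_min is not None:
            if _blur_variance(to_grayscale(crop)) < config.blur_variance_min:
                continue
        crop = transform.resize(crop, (config.output_size, config.output_size),
                                order=1, anti_aliasing=False, preserve_range=True)
        crops.append(np.clip(crop, 0.0, 1.0))
    return crops


def segment_image(rgb: np.ndarray,
                  config: PreprocessConfig = PreprocessConfig()) -> list[np.ndarray]:
    """Full segmentation of one photograph into per-seed crops."""
    gray = to_grayscale(rgb)
    mask = binarize(gray, config.threshold)
    return extract_seed_crops(apply_mask(rgb, mask), mask, config)


def preprocess_directory(in_dir, out_dir,
                         config: PreprocessConfig = PreprocessConfig()) -> pd.DataFrame:
    """Segment every image under ``in_dir/<class>/`` and write the crops.

    Returns (and saves) a manifest with one row per extracted crop.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    rows = []
    for cls_dir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        dest = out_dir / cls_dir.name
        dest.mkdir(parents=True, exist_ok=True)
        idx = 0
        for img_path in sorted(cls_dir.iterdir()):
            if img_path.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            for crop in segment_image(load_image(img_path), config):
                path = dest / f"{idx:05d}.png"
                save_image(crop, path)
                rows.append({"path": str(path), "label": cls_dir.name,
                             "split": "", "origin": "crop"})
                idx += 1
    manifest = pd.DataFrame(rows, columns=["path", "label", "split", "origin"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
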