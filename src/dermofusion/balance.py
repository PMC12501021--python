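"""Class-balancing augmentation planner and materialiser.

Minority classes are oversampled toward a common target T (about the size of
the dominant nevus class) by an integer per-class factor F_c = round(T/N_c),
the dominant class keeping F_c = 1. Augmented variants are produced by
label-preserving geometric and photometric transforms (flips, small
rotations, zoom, brightness/contrast/saturation) and every variant records
its parent image id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rescale, rotate

__all__ = [
    "augmentation_factor",
    "build_plan",
    "TransformSpec",
    "TransformRanges",
    "sample_transform",
    "apply_transform",
    "ImageRecord",
    "materialize_balanced_dataset",
]


def augmentation_factor(n_c: int, target: int) -> int:
    """Integer augmentation factor: round-half-up of target/N_c, floored at 1.

    The dominant class (N_c >= target) is never augmented (factor 1).
    """
    if n_c <= 0:
        raise ValueError("class count must be >= 1")
    if n_c >= target:
        return 1
    return max(1, int(math.floor(target / n_c + 0.5)))


def build_plan(inventory: Mapping[str, int], target: int,
               overrides: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Per-class augmentation plan: (class, original, factor, target).

    ``overrides`` pins the factor of specific classes, e.g. when mirroring a
    published balancing table whose factors differ from the T/N_c rule.
    """
    overrides = dict(overrides or {})
    for cls, f in overrides.items():
        if f < 1:
            raise ValueError(f"override factor for {cls} must be >= 1")
    rows = []
    for cls, n_c in inventory.items():
        if n_c < 1:
            raise ValueError(f"class {cls} has no images")
        factor = overrides.get(cls, augmentation_factor(n_c, target))
        rows.append({"class": cls, "original": int(n_c), "factor": int(factor),
                     "target": int(n_c) * int(factor)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransformRanges:
    """Clinically-plausible parameter ranges for the augmentations."""

    max_rotation: float = 30.0       # degrees
    zoom: tuple[float, float] = (0.9, 1.1)
    photometric: tuple[float, float] = (0.8, 1.2)


@dataclass(frozen=True)
class TransformSpec:
    """One concrete label-preserving transform.

    kind in {hflip, vflip, rotate, zoom, brightness, contrast, saturation};
    ``parameter`` is the angle (deg), scale, or multiplicative factor, and is
    ignored by the flips.
    """

    kind: str
    parameter: float = 0.0

    _KINDS = ("hflip", "vflip", "rotate", "zoom", "brightness", "contrast",
              "saturation")

    def validate(self, ranges: TransformRanges = TransformRanges()) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        p = self.parameter
        if self.kind == "rotate" and abs(p) > ranges.max_rotation:
            raise ValueError("rotation angle outside allowed range")
        if self.kind == "zoom" and not ranges.zoom[0] <= p <= ranges.zoom[1]:
            raise ValueError("zoom scale outside allowed range")
        if (self.kind in ("brightness", "contrast", "saturation")
                and not ranges.photometric[0] <= p <= ranges.photometric[1]):
            raise ValueError("photometric factor outside allowed range")


def sample_transform(rng: np.random.Generator,
                     ranges: TransformRanges = TransformRanges()) -> TransformSpec:
    kind = rng.choice(TransformSpec._KINDS)
    if kind == "rotate":
        p = float(rng.uniform(-ranges.max_rotation, ranges.max_rotation))
    elif kind == "zoom":
        p = float(rng.uniform(*ranges.zoom))
    elif kind in ("brightness", "contrast", "saturation"):
        p = float(rng.uniform(*ranges.photometric))
    else:
        p = 0.0
    return TransformSpec(kind=str(kind), parameter=p)


def _center_resize(img: np.ndarray, scale: float) -> np.ndarray:
    """Zoom keeping the canvas size; shrink pads by reflection."""
    h, w = img.shape[:2]
    scaled = rescale(img, scale, channel_axis=-1 if img.ndim == 3 else None,
                     preserve_range=True, anti_aliasing=scale < 1.0)
    sh, sw = scaled.shape[:2]
    if sh >= h and sw >= w:
        y0, x0 = (sh - h) // 2, (sw - w) // 2
        return scaled[y0:y0 + h, x0:x0 + w]
    py, px = max(0, h - sh), max(0, w - sw)
    pads = [(py // 2, py - py // 2), (px // 2, px - px // 2)]
    if img.ndim == 3:
        pads.append((0, 0))
    padded = np.pad(scaled, pads, mode="reflect")
    return padded[:h, :w]


def apply_transform(img: np.ndarray, spec: TransformSpec,
                    ranges: TransformRanges = TransformRanges()) -> np.ndarray:
    """Apply one transform; same dtype range and canvas size, deterministic."""
    spec.validate(ranges)
    img = np.asarray(img, dtype=float)
    if spec.kind == "hflip":
        out = img[:, ::-1]
    elif spec.kind == "vflip":
        out = img[::-1]
    elif spec.kind == "rotate":
        out = rotate(img, spec.parameter, mode="reflect", preserve_range=True)
    elif spec.kind == "zoom":
        out = _center_resize(img, spec.parameter)
    elif spec.kind == "brightness":
        out = img * spec.parameter
    elif spec.kind == "contrast":
        mean = img.mean()
        out = (img - mean) * spec.parameter + mean
    else:  # saturation
        hsv = rgb2hsv(np.clip(img / 255.0, 0, 1))
        hsv[..., 1] = np.clip(hsv[..., 1] * spec.parameter, 0, 1)
        out = hsv2rgb(hsv) * 255.0
    return np.clip(out, 0, 255).copy()


@dataclass
class ImageRecord:
    """One dataset entry; augmented variants point at their parent."""

    image_id: str
    label: str
    pixels: np.ndarray
    parent_id: str | None = None


def materialize_balanced_dataset(records: Sequence[ImageRecord],
                                 plan: pd.DataFrame, seed: int,
                                 ranges: TransformRanges = TransformRanges(),
                                 ) -> list[ImageRecord]:
    """Expand every class to exactly its planned target count.

    Each class keeps its originals and adds (F_c - 1) augmented variants per
    original, drawn from seeded random transforms; output ordering and pixel
    content are fully reproducible for a fixed seed.
    """
    plan_by_class = {row["class"]: row for _, row in plan.iterrows()}
    labels_present = {r.label for r in records}
    missing = labels_present - set(plan_by_class)
    if missing:
        raise ValueError(f"classes missing from plan: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    out: list[ImageRecord] = []
    for rec in records:
        out.append(rec)
    for rec in records:
        factor = int(plan_by_class[rec.label]["factor"])
        for k in range(factor - 1):
            spec = sample_transform(rng, ranges)
            aug = apply_transform(rec.pixels, spec, ranges)
            out.append(ImageRecord(image_id=f"{rec.image_id}_aug{k}",
                                   label=rec.label, pixels=aug,
                                   parent_id=rec.image_id))
    return out
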