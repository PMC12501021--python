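"""Synthetic dermoscopy-style image generator.

Real dermoscopic archives (HAM10000 / ISIC 2018 style) cannot ship with a
library, so this module renders small class-conditioned stand-ins: a skin-
toned background, one elliptical lesion with an irregular boundary whose hue
identifies its class, optional dark curved hair strokes with exact ground-
truth masks, and labelled manifests. The seven class hue bands are disjoint,
which makes the classes linearly separable in mean-RGB space — a property the
desk-scale learnability checks rely on.

Everything is a pure function of (spec, size, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

__all__ = [
    "CLASS_NAMES",
    "LesionSpec",
    "HairSpec",
    "class_hue_band",
    "generate_lesion_image",
    "draw_hairs",
    "generate_dataset",
]

CLASS_NAMES = ("AKIEC", "BCC", "BKL", "DF", "MEL", "NV", "VASC")

_DEFAULT_SKIN = np.array([224.0, 182.0, 150.0])


def class_hue_band(class_id: int) -> tuple[float, float]:
    """Disjoint HSV hue band for each of the seven classes (width 0.08)."""
    if not 0 <= class_id <= 6:
        raise ValueError("class_id must be in 0..6")
    center = 0.06 + 0.13 * class_id
    return (center - 0.04, center + 0.04)


@dataclass
class LesionSpec:
    """Parameters of one rendered lesion.

    size_fraction is the lesion area as a fraction of the canvas; the
    boundary irregularity amplitude perturbs the ellipse radius with a few
    low-frequency harmonics, emulating the lobulated borders of real lesions.
    """

    class_id: int
    skin_tone: np.ndarray = field(default_factory=lambda: _DEFAULT_SKIN.copy())
    size_fraction: float = 0.25
    irregularity: float = 0.10
    noise_sigma: float = 6.0
    saturation: float = 0.65
    value: float = 0.55

    def __post_init__(self):
        if not 0 < self.size_fraction <= 0.6:
            raise ValueError("size_fraction must be in (0, 0.6]")
        if not 0 <= self.class_id <= 6:
            raise ValueError("class_id must be in 0..6")


@dataclass
class HairSpec:
    """Parameters of the rendered hair overlay."""

    n_strokes: int = 5
    thickness: int = 1
    darkness: float = 90.0
    curvature: float = 0.25

    def __post_init__(self):
        if self.n_strokes < 0:
            raise ValueError("n_strokes must be >= 0")
        if not 1 <= self.thickness <= 3:
            raise ValueError("thickness must be 1..3 px")


def generate_lesion_image(spec: LesionSpec, size: tuple[int, int],
                          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion image; returns (H x W x 3 image, boolean truth mask)."""
    h, w = size
    rng = np.random.default_rng(seed)
    target_area = spec.size_fraction * h * w
    aspect = rng.uniform(0.7, 1.0)
    # pi * a * b = target_area with b = aspect * a
    a = np.sqrt(target_area / (np.pi * aspect))
    b = aspect * a
    if 2 * a * (1.0 + spec.irregularity) >= min(h, w):
        raise ValueError(f"canvas {h}x{w} too small for size_fraction "
                         f"{spec.size_fraction}")
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = (yy - cy) / b, (xx - cx) / a
    radius = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    wobble = np.zeros_like(theta)
    for harmonic in (2, 3, 5):
        wobble += (spec.irregularity / 3.0) * np.sin(
            harmonic * theta + rng.uniform(0, 2 * np.pi))
    mask = radius <= 1.0 + wobble

    lo, hi = class_hue_band(spec.class_id)
    hue = rng.uniform(lo + 0.01, hi - 0.01)
    lesion_rgb = hsv2rgb(np.array([[[hue, spec.saturation, spec.value]]]))[0, 0] * 255.0

    img = np.empty((h, w, 3))
    img[:] = spec.skin_tone
    img[mask] = lesion_rgb
    # soft inner darkening for a little texture
    inner = radius <= 0.55
    img[inner & mask] *= 0.92
    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255), mask


def draw_hairs(img: np.ndarray, spec: HairSpec,
               seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlay dark curved strokes; returns (image, exact stroke mask)."""
    rng = np.random.default_rng(seed)
    out = np.asarray(img, dtype=float).copy()
    h, w = out.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_strokes):
        # quadratic bezier across the canvas
        p0 = rng.uniform([0, 0], [h - 1, w - 1])
        direction = rng.uniform(0, np.pi)
        length = rng.uniform(0.5, 0.9) * min(h, w)
        p2 = p0 + length * np.array([np.sin(direction), np.cos(direction)])
        mid = (p0 + p2) / 2
        normal = np.array([np.cos(direction), -np.sin(direction)])
        p1 = mid + spec.curvature * length * rng.uniform(-1, 1) * normal
        ts = np.linspace(0, 1, 64)
        pts = ((1 - ts)[:, None] ** 2 * p0 + 2 * (ts * (1 - ts))[:, None] * p1
               + ts[:, None] ** 2 * p2)
        pts = np.clip(pts, [0, 0], [h - 1, w - 1]).round().astype(int)
        stroke = np.zeros((h, w), dtype=bool)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            stroke[rr, cc] = True
        if spec.thickness > 1:
            stroke = dilation(stroke, disk(spec.thickness - 1))
        mask |= stroke
    if mask.any():
        if out.ndim == 3:
            out[mask] = np.clip(out[mask] - spec.darkness, 0, 255)
        else:
            out[mask] = np.clip(out[mask] - spec.darkness, 0, 255)
    return out, mask


def generate_dataset(n_per_class, size: tuple[int, int], seed: int,
                     out_dir: str | Path | None = None,
                     hair_prob: float = 0.0,
                     ) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Generate a labelled seven-class dataset.

    n_per_class may be an int (balanced) or a length-7 sequence, allowing
    deliberately imbalanced inventories. Returns (images, labels, manifest);
    when ``out_dir`` is given the images are also written as PNG and the
    manifest's image_path points at them.
    """
    if np.isscalar(n_per_class):
        counts = [int(n_per_class)] * 7
    else:
        counts = [int(c) for c in n_per_class]
    if len(counts) != 7:
        raise ValueError("expected counts for exactly 7 classes")
    rng = np.random.default_rng(seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    idx = 0
    for class_id, n in enumerate(counts):
        for _ in range(n):
            sub = int(rng.integers(0, 2**31 - 1))
            # narrow size band: class identity is carried by hue, not area
            spec = LesionSpec(class_id=class_id,
                              size_fraction=float(rng.uniform(0.25, 0.35)))
            img, _ = generate_lesion_image(spec, size, sub)
            if hair_prob > 0 and rng.random() < hair_prob:
                img, _ = draw_hairs(img, HairSpec(), int(rng.integers(0, 2**31 - 1)))
            image_id = f"SYN_{idx:06d}"
            path = ""
            if out_dir is not None:
                from PIL import Image
                path = str(out_dir / f"{image_id}.png")
                Image.fromarray(img.astype(np.uint8)).save(path)
            images.append(img)
            labels.append(class_id)
            rows.append({"image_id": image_id, "image_path": path,
                         "label": CLASS_NAMES[class_id]})
            idx += 1
    manifest = pd.DataFrame(rows)
    return images, np.asarray(labels), manifest


def mean_hue(img: np.ndarray, mask: np.ndarray) -> float:
    """Mean HSV hue of the masked region (bands here avoid the wraparound)."""
    hsv = rgb2hsv(np.clip(np.asarray(img, dtype=float) / 255.0, 0, 1))
    return float(hsv[..., 0][mask].mean())
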