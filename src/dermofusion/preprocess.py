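"""Dermoscopy image enhancement and hair removal.

The enhancement stage combines an adaptive average filter (local smoothing
whose strength depends on the ratio of local variance to an assumed noise
variance) with Laplacian sharpening: the sharpened response is *added* to the
adaptively smoothed image and the result clipped back to [0, 255].

The hair-removal stage detects thin dark elongated structures by grayscale
morphological closing with rotated linear structuring elements, thresholds
the closing residual into a binary hair mask, and replaces masked pixels by
an inverse-Euclidean-distance weighted mean of nearby non-hair pixels.

Images are H x W (grayscale) or H x W x 3 (RGB) float/uint8 arrays with
values in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

__all__ = [
    "EnhancementConfig",
    "HairRemovalConfig",
    "estimate_noise_variance",
    "adaptive_average_filter",
    "laplacian_filter",
    "enhance_image",
    "detect_hair_mask",
    "inpaint_hair",
    "preprocess_pipeline",
]

LAPLACIAN_KERNELS = {
    "4-neighbor": np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float),
    "8-neighbor": np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float),
}

# Rec.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class EnhancementConfig:
    """Knobs for the two-stage enhancement.

    window: odd side of the local-statistics window (pixels).
    noise_var: assumed noise variance (intensity^2) or "auto" to estimate it
        as the median of the local-variance map.
    laplacian_kernel: "4-neighbor" or "8-neighbor" 3x3 kernel.
    clip_range: output intensity bounds.
    """

    window: int = 7
    noise_var: float | str = "auto"
    laplacian_kernel: str = "8-neighbor"
    clip_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.laplacian_kernel not in LAPLACIAN_KERNELS:
            raise ValueError(f"unknown laplacian kernel {self.laplacian_kernel!r}")
        if self.noise_var != "auto" and float(self.noise_var) < 0:
            raise ValueError("noise_var must be nonnegative or 'auto'")


@dataclass
class HairRemovalConfig:
    """Knobs for morphological hair detection and inpainting.

    se_length: length (px) of the linear structuring element.
    n_orientations: number of SE orientations spread uniformly over 180 deg.
    mask_threshold: "otsu" or a fixed numeric threshold on the closing
        residual (closed - original, in intensity units).
    dilation_radius: disk radius (px) used to dilate the detected mask so the
        inpainting also covers hair fringes.
    inpaint_min_neighbors: minimum number of donor (non-hair) pixels the
        inpainting window must contain before the weighted mean is taken.
    """

    se_length: int = 17
    n_orientations: int = 8
    mask_threshold: str | float = "otsu"
    dilation_radius: int = 1
    inpaint_min_neighbors: int = 4

    def __post_init__(self):
        if self.se_length < 3:
            raise ValueError("se_length must be >= 3")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if self.inpaint_min_neighbors < 1:
            raise ValueError("inpaint_min_neighbors must be >= 1")


def _as_float(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("image must be HxW or HxWxC")
    return img


def _local_mean_var(channel: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    mu = ndimage.uniform_filter(channel, size=w, mode="reflect")
    mu2 = ndimage.uniform_filter(channel * channel, size=w, mode="reflect")
    var = np.maximum(mu2 - mu * mu, 0.0)
    return mu, var


def estimate_noise_variance(img: np.ndarray, window: int = 7) -> float:
    """Median of the local-variance map over ``window x window`` neighbourhoods.

    The median is robust to the lesion itself: lesion borders inflate local
    variance only in a minority of windows, so the median tracks the flat
    skin background. RGB images use the mean over per-channel estimates.
    """
    img = _as_float(img)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    h, w = img.shape[:2]
    if h < window or w < window:
        raise ValueError(f"image {h}x{w} smaller than the {window}x{window} window")
    if img.ndim == 3:
        return float(np.mean([estimate_noise_variance(img[..., c], window)
                              for c in range(img.shape[2])]))
    _, var = _local_mean_var(img, window)
    return float(np.median(var))


def adaptive_average_filter(img: np.ndarray, noise_var: float,
                            window: int = 7) -> np.ndarray:
    """Adaptive local-mean smoothing.

    out = mu_L + clamp((sigma_L^2 - sigma_N^2) / sigma_L^2, 0, 1) * (I - mu_L)

    High local variance relative to the noise floor preserves the pixel
    (edges); local variance at or below the noise floor pulls the pixel to
    the local mean. Reflect padding at borders; RGB handled per channel.
    """
    img = _as_float(img)
    if noise_var < 0:
        raise ValueError("noise_var must be nonnegative")
    if img.ndim == 3:
        return np.stack([adaptive_average_filter(img[..., c], noise_var, window)
                         for c in range(img.shape[2])], axis=-1)
    mu, var = _local_mean_var(img, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(var > 0, (var - noise_var) / var, 0.0)
    ratio = np.clip(ratio, 0.0, 1.0)
    return mu + ratio * (img - mu)


def laplacian_filter(img: np.ndarray, kernel: str = "8-neighbor") -> np.ndarray:
    """Signed 3x3 Laplacian response (reflect padding); may be negative."""
    img = _as_float(img)
    k = LAPLACIAN_KERNELS[kernel]
    if img.ndim == 3:
        return np.stack([ndimage.convolve(img[..., c], k, mode="reflect")
                         for c in range(img.shape[2])], axis=-1)
    return ndimage.convolve(img, k, mode="reflect")


def enhance_image(img: np.ndarray, cfg: EnhancementConfig | None = None) -> np.ndarray:
    """Adaptive smoothing followed by additive Laplacian sharpening.

    The Laplacian is computed on the smoothed image and added to it, then the
    sum is clipped to ``cfg.clip_range``.
    """
    cfg = cfg or EnhancementConfig()
    img = _as_float(img)
    nv = (estimate_noise_variance(img, cfg.window) if cfg.noise_var == "auto"
          else float(cfg.noise_var))
    smoothed = adaptive_average_filter(img, nv, cfg.window)
    lap = laplacian_filter(smoothed, cfg.laplacian_kernel)
    return np.clip(smoothed + lap, *cfg.clip_range)


def to_luminance(img: np.ndarray) -> np.ndarray:
    img = _as_float(img)
    if img.ndim == 2:
        return img
    return img[..., :3] @ _LUMA


def _line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Binary line structuring element of ``length`` px at ``angle_deg``."""
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2.0
    r0 = int(round(half - half * np.sin(theta)))
    c0 = int(round(half - half * np.cos(theta)))
    r1 = int(round(half + half * np.sin(theta)))
    c1 = int(round(half + half * np.cos(theta)))
    fp = np.zeros((length, length), dtype=bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    fp[rr, cc] = True
    return fp


def detect_hair_mask(img: np.ndarray, cfg: HairRemovalConfig | None = None) -> np.ndarray:
    """Binary hair mask from multi-orientation morphological closing.

    Hairs are thin dark curvilinear structures: grayscale closing with a
    linear structuring element fills them, so the residual (closed - original)
    is large exactly on hair pixels. The per-pixel maximum of the closing over
    ``n_orientations`` rotated elements captures hairs at any angle. The
    residual is thresholded (Otsu by default) and dilated slightly.
    """
    cfg = cfg or HairRemovalConfig()
    gray = to_luminance(img)
    h, w = gray.shape
    if cfg.se_length > min(h, w):
        raise ValueError("se_length exceeds the smaller image dimension")
    closed_max = np.full_like(gray, -np.inf)
    angles = np.arange(cfg.n_orientations) * (180.0 / cfg.n_orientations)
    for angle in angles:
        fp = _line_footprint(cfg.se_length, angle)
        dil = ndimage.grey_dilation(gray, footprint=fp, mode="reflect")
        closed = ndimage.grey_erosion(dil, footprint=fp, mode="reflect")
        np.maximum(closed_max, closed, out=closed_max)
    residual = np.maximum(closed_max - gray, 0.0)
    if cfg.mask_threshold == "otsu":
        thr = threshold_otsu(residual) if residual.max() > 0 else np.inf
    else:
        thr = float(cfg.mask_threshold)
    mask = residual > thr
    if cfg.dilation_radius > 0 and mask.any():
        mask = dilation(mask, disk(cfg.dilation_radius))
    return mask.astype(np.uint8)


def inpaint_hair(img: np.ndarray, mask: np.ndarray,
                 cfg: HairRemovalConfig | None = None) -> np.ndarray:
    """Replace masked pixels by an inverse-distance weighted mean of donors.

    For each masked pixel the square search window grows until it contains at
    least ``inpaint_min_neighbors`` non-hair pixels; those donors are averaged
    with weights 1/d (Euclidean distance). Unmasked pixels pass through
    untouched; a shared mask is applied to every channel.
    """
    cfg = cfg or HairRemovalConfig()
    img = _as_float(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape must match image spatial dims")
    if mask.all():
        raise ValueError("mask covers the whole image: no donor pixels")
    if not mask.any():
        return img.copy()
    out = img.copy()
    h, w = mask.shape
    donors_ok = ~mask
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        r = 1
        while True:
            y0, y1 = max(0, y - r), min(h, y + r + 1)
            x0, x1 = max(0, x - r), min(w, x + r + 1)
            sub_ok = donors_ok[y0:y1, x0:x1]
            if sub_ok.sum() >= cfg.inpaint_min_neighbors:
                break
            if y0 == 0 and x0 == 0 and y1 == h and x1 == w:
                break  # whole image reached; use whatever donors exist
            r += 1
        dy, dx = np.nonzero(sub_ok)
        dist = np.hypot(dy + y0 - y, dx + x0 - x)
        wts = 1.0 / dist
        vals = img[dy + y0, dx + x0]
        if img.ndim == 3:
            out[y, x] = (wts[:, None] * vals).sum(axis=0) / wts.sum()
        else:
            out[y, x] = (wts * vals).sum() / wts.sum()
    return out


def preprocess_pipeline(img: np.ndarray,
                        e_cfg: EnhancementConfig | None = None,
                        h_cfg: HairRemovalConfig | None = None) -> np.ndarray:
    """Enhancement, then hair detection, then inpainting — deterministic."""
    e_cfg = e_cfg or EnhancementConfig()
    h_cfg = h_cfg or HairRemovalConfig()
    enhanced = enhance_image(img, e_cfg)
    mask = detect_hair_mask(enhanced, h_cfg)
    return inpaint_hair(enhanced, mask, h_cfg)
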