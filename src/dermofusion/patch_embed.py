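"""Patchification and token embedding for the transformer branch.

A 600 x 450 enhanced image is tiled into non-overlapping 30 x 30 patches
(N = H*W/P^2 = 300 of them), each flattened patch is linearly projected to a
D-dimensional token, and a fixed sinusoidal positional encoding is added:

    PE(pos, 2i)   = sin(pos / base^(2i/D))
    PE(pos, 2i+1) = cos(pos / base^(2i/D))

with frequency base 1000 (a deliberate departure from the conventional
10000, kept configurable). Positions index patches in row-major order.
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = [
    "num_patches",
    "patchify",
    "unpatchify",
    "sinusoidal_pe",
    "embed_tokens",
    "PatchEmbed",
]


def num_patches(height: int, width: int, patch: int) -> int:
    """Number of non-overlapping patch tiles: H*W/P^2 (dims must divide)."""
    if height % patch or width % patch:
        raise ValueError(f"{height}x{width} not divisible by patch {patch}; "
                         "resize upstream, patchify never resizes")
    return (height // patch) * (width // patch)


def patchify(img: np.ndarray, patch: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Row-major lossless tiling -> (N, P*P*C) matrix plus (rows, cols)."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    h, w, c = img.shape
    n = num_patches(h, w, patch)
    rows, cols = h // patch, w // patch
    tiles = (img.reshape(rows, patch, cols, patch, c)
             .transpose(0, 2, 1, 3, 4)
             .reshape(n, patch * patch * c))
    return tiles, (rows, cols)


def unpatchify(patches: np.ndarray, grid: tuple[int, int], patch: int,
               channels: int = 3) -> np.ndarray:
    """Inverse of :func:`patchify` (bit-exact round trip)."""
    rows, cols = grid
    img = (patches.reshape(rows, cols, patch, patch, channels)
           .transpose(0, 2, 1, 3, 4)
           .reshape(rows * patch, cols * patch, channels))
    return img


def sinusoidal_pe(n: int, dim: int, base: float = 1000.0) -> np.ndarray:
    """Fixed sine/cosine positional-encoding table of shape (n, dim).

    Even columns carry sines, odd columns the matching cosines; all entries
    lie in [-1, 1] and the table is a pure function of (n, dim, base).
    """
    if dim % 2:
        raise ValueError("embedding dim must be even")
    pos = np.arange(n)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / base ** (2 * i / dim)
    table = np.empty((n, dim))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return table


def embed_tokens(patches: np.ndarray, weight: np.ndarray,
                 pe: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Linear projection of flattened patches plus positional encoding.

    weight maps P*P*C -> D; pe must have one row per patch. Each token
    depends only on its own patch (pre-attention locality).
    """
    patches = np.asarray(patches, dtype=float)
    if pe.shape[0] != patches.shape[0]:
        raise ValueError("positional table rows must equal patch count")
    tokens = patches @ weight
    if bias is not None:
        tokens = tokens + bias
    if tokens.shape[1] != pe.shape[1]:
        raise ValueError("projection dim does not match positional table")
    return tokens + pe


class PatchEmbed(nn.Module):
    """Trainable patch-to-token projection with fixed positional encoding."""

    def __init__(self, patch: int, channels: int, dim: int,
                 rng: np.random.Generator, pe_base: float = 1000.0):
        super().__init__()
        self.patch = patch
        self.channels = channels
        self.dim = dim
        self.pe_base = pe_base
        self.proj = nn.Linear(patch * patch * channels, dim, rng)

    def forward(self, img: np.ndarray) -> tuple[nn.Tensor, tuple[int, int]]:
        tiles, grid = patchify(img, self.patch)
        tokens = self.proj(nn.Tensor(tiles))
        pe = sinusoidal_pe(tiles.shape[0], self.dim, self.pe_base)
        return tokens + nn.Tensor(pe), grid
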