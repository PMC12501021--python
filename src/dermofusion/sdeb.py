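"""Spatial Detail Enhancement Block (SDEB).

Patch tokens lose the local continuity of the original image; the SDEB
restores it by convolving the token grid with three parallel multi-scale
branches — 3x3/64 (fine texture), 5x5/128 (meso-scale context), 7x7/256
(refinement) — each followed by ReLU. The branch maps carry different channel
counts, so each is aligned to the fusion width C by a 1x1 projection before
the element-wise sum; a final ReLU(1x1 conv) compresses the sum into C
channels. Spatial dims are preserved throughout ('same' padding).

The block operates on the (rows x cols) patch grid: the N x D token sequence
is reshaped to a rows x cols x D map, convolved, and flattened back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["SDEBConfig", "SDEB", "sdeb_tokens"]


@dataclass
class SDEBConfig:
    branches: tuple[tuple[int, int], ...] = ((3, 64), (5, 128), (7, 256))
    fusion_channels: int = 256

    def __post_init__(self):
        if len(self.branches) != 3:
            raise ValueError("SDEB has exactly three branches")
        if self.fusion_channels < 1:
            raise ValueError("fusion_channels must be >= 1")


class SDEB(nn.Module):
    def __init__(self, in_channels: int, cfg: SDEBConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.fusion_channels
        self.branch_convs = [nn.Conv2d(in_channels, filters, kernel, rng)
                             for kernel, filters in cfg.branches]
        self.aligners = [nn.Conv2d(filters, c, 1, rng)
                         for _, filters in cfg.branches]
        self.fuse = nn.Conv2d(c, c, 1, rng)
        self.min_spatial = max(k for k, _ in cfg.branches)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """x: (N, C_in, H', W') feature map -> (N, C, H', W')."""
        h, w = x.shape[2], x.shape[3]
        if h < self.min_spatial or w < self.min_spatial:
            raise ValueError(f"spatial dims {h}x{w} below the largest kernel "
                             f"({self.min_spatial})")
        branches = [align(conv(x).relu())
                    for conv, align in zip(self.branch_convs, self.aligners)]
        total = branches[0] + branches[1] + branches[2]
        return self.fuse(total).relu()

    def branch_activations(self, x: nn.Tensor) -> list[np.ndarray]:
        """Pre-alignment ReLU branch outputs (internal taps for testing)."""
        return [conv(x).relu().data for conv in self.branch_convs]


def sdeb_tokens(block: SDEB, tokens: nn.Tensor,
                grid: tuple[int, int]) -> nn.Tensor:
    """Apply the SDEB to an N x D token sequence laid out on its patch grid."""
    rows, cols = grid
    n, d = tokens.shape
    if n != rows * cols:
        raise ValueError("token count does not match grid")
    fmap = tokens.reshape(rows, cols, d).transpose(2, 0, 1).reshape(1, d, rows, cols)
    out = block(fmap)
    c = out.shape[1]
    return out.reshape(c, rows * cols).transpose(1, 0)
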