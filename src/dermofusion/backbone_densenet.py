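"""Declarative builder for DenseNet-style backbones.

The backbone is described by an ordered table of stages (initial convolution,
max pooling, dense blocks, transitions, removals) from which a forward-
capable network is built. Two tables ship with the package: the standard
DenseNet169 feature extractor (dense blocks of 6/12/32/32 layers, 7x7/64
stem) and a pruned variant for dermoscopy (3x3/32 stem, dense block 3 cut to
16 layers, dense block 4 removed) that cuts the parameter count by well over
half. Dense connectivity is literal: each layer inside a block receives the
concatenation of the block input and all previous layer outputs, so layer l
sees ``block_in + (l-1) * growth`` channels.

Unstated construction details follow DenseNet convention: growth rate 32,
BN-ReLU-Conv ordering with a 4*growth bottleneck, transition compression
0.5, and global average pooling after the final retained stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.tensor import Tensor

__all__ = [
    "StageSpec",
    "ArchitectureTable",
    "original_densenet169_table",
    "enhanced_densenet169_table",
    "tiny_backbone_table",
    "DenseNetBackbone",
    "build_backbone",
    "count_parameters",
    "backbone_forward",
]


@dataclass(frozen=True)
class StageSpec:
    name: str
    kind: str                 # conv | pool | dense_block | transition | removed
    kernel: int = 0
    filters: int = 0          # conv: out channels; dense_block: growth rate
    stride: int = 1
    repeat: int = 0           # dense_block: number of conv layers


@dataclass(frozen=True)
class ArchitectureTable:
    variant: str
    input_size: int
    stages: tuple[StageSpec, ...]


def original_densenet169_table() -> ArchitectureTable:
    return ArchitectureTable(
        variant="original", input_size=224,
        stages=(
            StageSpec("initial_conv", "conv", kernel=7, filters=64, stride=2),
            StageSpec("pool", "pool", kernel=3, stride=2),
            StageSpec("dense_block_1", "dense_block", filters=32, repeat=6),
            StageSpec("transition_1", "transition"),
            StageSpec("dense_block_2", "dense_block", filters=32, repeat=12),
            StageSpec("transition_2", "transition"),
            StageSpec("dense_block_3", "dense_block", filters=32, repeat=32),
            StageSpec("transition_3", "transition"),
            StageSpec("dense_block_4", "dense_block", filters=32, repeat=32),
        ),
    )


def enhanced_densenet169_table() -> ArchitectureTable:
    """Pruned dermoscopy variant: smaller stem, shorter block 3, no block 4."""
    return ArchitectureTable(
        variant="enhanced", input_size=224,
        stages=(
            StageSpec("initial_conv", "conv", kernel=3, filters=32, stride=2),
            StageSpec("pool", "pool", kernel=3, stride=2),
            StageSpec("dense_block_1", "dense_block", filters=32, repeat=6),
            StageSpec("transition_1", "transition"),
            StageSpec("dense_block_2", "dense_block", filters=32, repeat=12),
            StageSpec("transition_2", "transition"),
            StageSpec("dense_block_3", "dense_block", filters=32, repeat=16),
            StageSpec("transition_3", "transition"),
            StageSpec("dense_block_4", "removed"),
        ),
    )


def tiny_backbone_table(input_size: int = 32, growth: int = 8) -> ArchitectureTable:
    """Desk-scale table for smoke training and fast end-to-end tests."""
    return ArchitectureTable(
        variant="tiny", input_size=input_size,
        stages=(
            StageSpec("initial_conv", "conv", kernel=3, filters=2 * growth, stride=2),
            StageSpec("dense_block_1", "dense_block", filters=growth, repeat=2),
            StageSpec("transition_1", "transition"),
            StageSpec("dense_block_2", "dense_block", filters=growth, repeat=2),
        ),
    )


class _DenseLayer(nn.Module):
    """BN-ReLU-Conv1x1(bottleneck) -> BN-ReLU-Conv3x3(growth)."""

    def __init__(self, in_ch: int, growth: int, rng: np.random.Generator,
                 bottleneck: int = 4):
        super().__init__()
        mid = bottleneck * growth
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, mid, 1, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, growth, 3, rng, bias=False)
        self.in_channels = in_ch

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv1(self.bn1(x).relu())
        return self.conv2(self.bn2(out).relu())


class _DenseBlock(nn.Module):
    def __init__(self, in_ch: int, growth: int, n_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        self.layers = [_DenseLayer(in_ch + i * growth, growth, rng)
                       for i in range(n_layers)]
        self.out_channels = in_ch + n_layers * growth

    @property
    def layer_input_channels(self) -> list[int]:
        return [layer.in_channels for layer in self.layers]

    def forward(self, x: Tensor) -> Tensor:
        feats = x
        for layer in self.layers:
            new = layer(feats)
            feats = Tensor.concat([feats, new], axis=1)
        return feats


class _Transition(nn.Module):
    """BN-ReLU-Conv1x1 (compression 0.5) followed by 2x2 average pooling."""

    def __init__(self, in_ch: int, rng: np.random.Generator,
                 compression: float = 0.5):
        super().__init__()
        self.out_channels = max(int(in_ch * compression), 1)
        self.bn = nn.BatchNorm2d(in_ch)
        self.conv = nn.Conv2d(in_ch, self.out_channels, 1, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        out = self.conv(self.bn(x).relu())
        return out.avg_pool2d(2)


class DenseNetBackbone(nn.Module):
    def __init__(self, table: ArchitectureTable, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.table = table
        self.stages: list[nn.Module | StageSpec] = []
        self.dense_blocks: dict[str, _DenseBlock] = {}
        self._modules_in_order: list[tuple[str, nn.Module]] = []
        ch = 3
        for spec in table.stages:
            if spec.kind == "removed":
                continue
            if spec.kind == "conv":
                mod = nn.Conv2d(ch, spec.filters, spec.kernel, rng,
                                stride=spec.stride, bias=False)
                ch = spec.filters
            elif spec.kind == "pool":
                mod = _MaxPoolStage(spec.kernel, spec.stride)
            elif spec.kind == "dense_block":
                mod = _DenseBlock(ch, spec.filters, spec.repeat, rng)
                ch = mod.out_channels
                self.dense_blocks[spec.name] = mod
            elif spec.kind == "transition":
                mod = _Transition(ch, rng)
                ch = mod.out_channels
            else:
                raise ValueError(f"unknown stage kind {spec.kind!r}")
            self._modules_in_order.append((spec.name, mod))
        self.stage_modules = [m for _, m in self._modules_in_order]
        self.out_channels = ch

    def forward(self, img: np.ndarray | Tensor) -> Tensor:
        """Image (HxWx3, [0,255]) or NCHW tensor -> flat feature vector."""
        if isinstance(img, Tensor):
            x = img
        else:
            img = np.asarray(img, dtype=float)
            if img.ndim != 3 or img.shape[2] != 3:
                raise ValueError("expected an HxWx3 image")
            h, w = img.shape[:2]
            if h != self.table.input_size or w != self.table.input_size:
                raise ValueError(f"expected {self.table.input_size}x"
                                 f"{self.table.input_size} input, got {h}x{w}")
            x = Tensor((img / 255.0 - 0.5).transpose(2, 0, 1)[None])
        for mod in self.stage_modules:
            x = mod(x)
        # global average pooling over the spatial dims
        return x.mean(axis=(2, 3)).reshape(x.shape[0], x.shape[1])


class _MaxPoolStage(nn.Module):
    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        return x.max_pool2d(self.kernel, self.stride, padding=(self.kernel - 1) // 2)


def build_backbone(table: ArchitectureTable, seed: int = 0) -> DenseNetBackbone:
    return DenseNetBackbone(table, seed)


def count_parameters(model: nn.Module) -> int:
    """Exact trainable parameter count."""
    return model.num_parameters()


def backbone_forward(model: DenseNetBackbone, img: np.ndarray) -> np.ndarray:
    """Deterministic eval-mode feature extraction; returns a 1-D vector."""
    model.eval()
    return model(img).data.ravel()
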