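"""The full hybrid model: transformer branch + DenseNet branch + fusion head.

One preprocessed RGB image feeds two parallel streams. The transformer
branch resizes to 600 x 450, patchifies into 30 x 30 tokens with sinusoidal
positional encodings, restores local detail with the SDEB, and runs six
encoder blocks before flattening all tokens. The CNN branch resizes to
224 x 224 and extracts a pooled feature vector from the pruned DenseNet169.
Each flattened vector is linearly projected to a shared fusion dimension and
the two are combined by element-wise addition; a LayerNorm ->
dropout -> dense -> dropout -> dense(7) -> softmax head yields the
seven-class probability vector.

A desk-scale configuration (small canvas, few tokens, shallow blocks) keeps
training and end-to-end tests tractable on one CPU; the architecture is
identical, only the sizes shrink.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import nn
from .backbone_densenet import (ArchitectureTable, DenseNetBackbone,
                                enhanced_densenet169_table, tiny_backbone_table)
from .evit_encoder import EncoderConfig, EncoderStack, flatten_tokens
from .nn.tensor import Tensor, cross_entropy, softmax
from .patch_embed import PatchEmbed
from .sdeb import SDEB, SDEBConfig, sdeb_tokens

__all__ = [
    "FusionConfig",
    "HybridConfig",
    "TrainConfig",
    "HybridModel",
    "fuse_features",
    "hybrid_forward",
    "fit_smoke",
    "tiny_config",
    "default_config",
]


@dataclass
class FusionConfig:
    fusion_dim: int = 1024
    head_hidden: int = 256
    dropout: float = 0.1
    n_classes: int = 7


@dataclass
class HybridConfig:
    vit_size: tuple[int, int] = (450, 600)   # (H, W) for the patch branch
    patch: int = 30
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    sdeb: SDEBConfig = field(default_factory=SDEBConfig)
    backbone: ArchitectureTable = field(default_factory=enhanced_densenet169_table)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seed: int = 0

    def __post_init__(self):
        if self.vit_size[0] % self.patch or self.vit_size[1] % self.patch:
            raise ValueError("vit_size must be divisible by patch")
        if self.encoder.dim != self.sdeb.fusion_channels:
            raise ValueError("encoder dim must equal SDEB fusion channels")


def default_config() -> HybridConfig:
    return HybridConfig()


def tiny_config(seed: int = 0) -> HybridConfig:
    """Desk-scale configuration used by the smoke-training harness."""
    return HybridConfig(
        vit_size=(32, 32), patch=4,
        encoder=EncoderConfig(n_blocks=2, heads=2, dim=16, mlp_ratio=2,
                              dropout=0.0),
        sdeb=SDEBConfig(branches=((3, 8), (5, 12), (7, 16)), fusion_channels=16),
        backbone=tiny_backbone_table(input_size=32, growth=8),
        fusion=FusionConfig(fusion_dim=32, head_hidden=32, dropout=0.0),
        seed=seed,
    )


def fuse_features(f_evit: Tensor | np.ndarray, f_dense: Tensor | np.ndarray,
                  proj_evit: nn.Linear | None = None,
                  proj_dense: nn.Linear | None = None) -> Tensor:
    """Element-wise additive fusion of the two branch vectors.

    With projections omitted the vectors must already share a dimension
    (identity projections).
    """
    a = f_evit if isinstance(f_evit, Tensor) else Tensor(np.asarray(f_evit, float))
    b = f_dense if isinstance(f_dense, Tensor) else Tensor(np.asarray(f_dense, float))
    if proj_evit is not None:
        a = proj_evit(a)
    if proj_dense is not None:
        b = proj_dense(b)
    if a.shape != b.shape:
        raise ValueError(f"fusion dim mismatch: {a.shape} vs {b.shape}")
    return a + b


class ClassifierHead(nn.Module):
    """LN -> flatten -> dropout -> dense -> dropout -> dense(K) -> softmax."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(cfg.fusion_dim)
        self.drop1 = nn.Dropout(cfg.dropout, np.random.default_rng(
            rng.integers(0, 2**31 - 1)))
        self.fc1 = nn.Linear(cfg.fusion_dim, cfg.head_hidden, rng)
        self.drop2 = nn.Dropout(cfg.dropout, np.random.default_rng(
            rng.integers(0, 2**31 - 1)))
        self.fc2 = nn.Linear(cfg.head_hidden, cfg.n_classes, rng)

    def logits(self, fused: Tensor) -> Tensor:
        x = self.norm(fused).reshape(1, -1) if fused.ndim == 1 else self.norm(fused)
        x = self.drop1(x)
        x = self.fc1(x)
        x = self.drop2(x)
        return self.fc2(x)

    def forward(self, fused: Tensor) -> Tensor:
        return softmax(self.logits(fused), axis=-1)


class HybridModel(nn.Module):
    def __init__(self, cfg: HybridConfig | None = None):
        super().__init__()
        cfg = cfg or HybridConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, w = cfg.vit_size
        self.grid = (h // cfg.patch, w // cfg.patch)
        n_tokens = self.grid[0] * self.grid[1]
        self.patch_embed = PatchEmbed(cfg.patch, 3, cfg.encoder.dim, rng)
        self.sdeb = SDEB(cfg.encoder.dim, cfg.sdeb, rng)
        self.encoder = EncoderStack(cfg.encoder, rng, n_tokens=n_tokens)
        flat_dim = n_tokens * cfg.sdeb.fusion_channels
        if cfg.encoder.token_upsample and cfg.encoder.n_blocks > 1:
            flat_dim *= 2 ** (cfg.encoder.n_blocks - 1)
        self.backbone = DenseNetBackbone(cfg.backbone,
                                         seed=int(rng.integers(0, 2**31 - 1)))
        self.proj_evit = nn.Linear(flat_dim, cfg.fusion.fusion_dim, rng)
        self.proj_dense = nn.Linear(self.backbone.out_channels,
                                    cfg.fusion.fusion_dim, rng)
        self.head = ClassifierHead(cfg.fusion, rng)

    # ----------------------------------------------------------------- passes
    def _branch_inputs(self, img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        img = np.asarray(img, dtype=float)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("expected an HxWx3 RGB image")
        h, w = self.cfg.vit_size
        s = self.cfg.backbone.input_size
        vit_img = (img if img.shape[:2] == (h, w)
                   else resize(img, (h, w), preserve_range=True,
                               anti_aliasing=True))
        cnn_img = (img if img.shape[:2] == (s, s)
                   else resize(img, (s, s), preserve_range=True,
                               anti_aliasing=True))
        return vit_img, cnn_img

    def logits(self, img: np.ndarray) -> Tensor:
        vit_img, cnn_img = self._branch_inputs(img)
        tokens, grid = self.patch_embed(vit_img / 255.0 - 0.5)
        tokens = sdeb_tokens(self.sdeb, tokens, grid)
        tokens = self.encoder(tokens)
        f_evit = flatten_tokens(tokens)
        f_dense = self.backbone(cnn_img).reshape(-1)
        fused = fuse_features(f_evit, f_dense, self.proj_evit, self.proj_dense)
        return self.head.logits(fused)

    def forward(self, img: np.ndarray) -> Tensor:
        return softmax(self.logits(img), axis=-1).reshape(-1)

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        """Eval-mode class probabilities, shape (7,), summing to one."""
        was_training = self.training
        self.eval()
        probs = self.forward(img).data
        self.train(was_training)
        return probs

    def logits_batch(self, images: list[np.ndarray]) -> Tensor:
        return Tensor.concat([self.logits(img) for img in images], axis=0)


def hybrid_forward(img: np.ndarray, model: HybridModel,
                   eval_mode: bool = True) -> np.ndarray:
    """End-to-end probability vector for one preprocessed image."""
    if eval_mode:
        return model.predict_proba(img)
    return model(img).data


# ----------------------------------------------------------------- training
@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 14
    lr: float = 3e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def fit_smoke(images: list[np.ndarray], labels: np.ndarray,
              cfg: TrainConfig | None = None,
              model: HybridModel | None = None,
              target_accuracy: float | None = None,
              ) -> tuple[HybridModel, dict[str, list[float]]]:
    """Desk-scale cross-entropy training loop (Adam).

    Returns the trained model and a history dict with per-epoch mean loss
    and training accuracy. ``epochs=0`` leaves the weights bit-identical to
    their initialisation. If ``target_accuracy`` is given, training stops
    early once the epoch's training accuracy reaches it.
    """
    if len(images) == 0:
        raise ValueError("empty dataset")
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, dtype=int)
    model = model or HybridModel(tiny_config(seed=cfg.seed))
    optimizer = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    n = len(images)
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.logits_batch([images[i] for i in idx])
            loss = cross_entropy(logits, labels[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == labels[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(100.0 * correct / n)
        if target_accuracy is not None and history["accuracy"][-1] >= target_accuracy:
            break
    model.eval()
    return model, history


def training_accuracy(model: HybridModel, images: list[np.ndarray],
                      labels: np.ndarray) -> float:
    """Eval-mode accuracy (%) of the model on its own training set."""
    preds = [int(np.argmax(model.predict_proba(img))) for img in images]
    return 100.0 * float(np.mean(np.asarray(preds) == np.asarray(labels)))
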