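"""Enhanced ViT encoder: six transformer blocks with multi-head self-attention.

Each block applies layer normalisation both before and after the attention
operation, with residual connections around attention and the GELU MLP:

    h   = x + MHSA(LN(x))
    h'  = LN(h)
    out = h' + MLP(h')

With attention and MLP weights zeroed this reduces to iterated layer
normalisation, which the tests exploit as a closed-form check. Attention is
the scaled dot product softmax(Q K^T / sqrt(d_k)) V; heads act on D/heads
slices of the jointly projected tokens and are concatenated and linearly
transformed. Token count is constant through the stack by default; an
optional learned token-upsampling stage can grow it between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, softmax

__all__ = [
    "EncoderConfig",
    "scaled_dot_attention",
    "layer_norm",
    "MultiHeadSelfAttention",
    "MLPBlock",
    "EncoderBlock",
    "EncoderStack",
    "TokenUpsample",
    "flatten_tokens",
]


@dataclass
class EncoderConfig:
    n_blocks: int = 6
    heads: int = 8
    dim: int = 256
    mlp_ratio: int = 4
    dropout: float = 0.1
    eps: float = 1e-6
    token_upsample: bool = False

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")


def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                         return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V on plain arrays; rows sum to one."""
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    d_k = q.shape[-1]
    if d_k == 0:
        raise ValueError("key dimension must be positive")
    logits = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    weights = np.exp(logits)
    weights /= weights.sum(axis=-1, keepdims=True)
    out = weights @ v
    return (out, weights) if return_weights else out


def layer_norm(x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """(x - mu) / sqrt(sigma^2 + eps) over the trailing feature axis."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.dim
        self.heads = cfg.heads
        self.d_head = d // cfg.heads
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, d = x.shape
        q, k, v = self.wq(x), self.wk(x), self.wv(x)

        def split(t: Tensor) -> Tensor:  # (n, d) -> (heads, n, d_head)
            return t.reshape(n, self.heads, self.d_head).transpose(1, 0, 2)

        qh, kh, vh = split(q), split(k), split(v)
        logits = (qh @ kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(logits, axis=-1)
        self.last_attention = attn.data.copy()
        out = attn @ vh                       # (heads, n, d_head)
        out = out.transpose(1, 0, 2).reshape(n, d)
        return self.wo(out)


class MLPBlock(nn.Module):
    """Two dense layers with GELU: W2 . GELU(W1 . x + b1) + b2."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        hidden = cfg.dim * cfg.mlp_ratio
        self.fc1 = nn.Linear(cfg.dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, cfg.dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class EncoderBlock(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.ln_pre = nn.LayerNorm(cfg.dim, eps=cfg.eps)
        self.ln_post = nn.LayerNorm(cfg.dim, eps=cfg.eps)
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.mlp = MLPBlock(cfg, rng)
        self.drop = nn.Dropout(cfg.dropout, np.random.default_rng(
            rng.integers(0, 2**31 - 1)))

    def forward(self, x: Tensor) -> Tensor:
        h = x + self.drop(self.attn(self.ln_pre(x)))
        h = self.ln_post(h)
        return h + self.drop(self.mlp(h))


class TokenUpsample(nn.Module):
    """Learned doubling of the token count (linear mix along the token axis)."""

    def __init__(self, n_in: int, rng: np.random.Generator):
        super().__init__()
        self.mix = nn.Linear(n_in, 2 * n_in, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.mix(x.transpose(1, 0)).transpose(1, 0)


class EncoderStack(nn.Module):
    """``n_blocks`` sequential encoder blocks; deterministic in eval mode."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 n_tokens: int | None = None):
        super().__init__()
        self.cfg = cfg
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.upsamplers: list[TokenUpsample] = []
        if cfg.token_upsample:
            if n_tokens is None:
                raise ValueError("token_upsample requires n_tokens")
            n = n_tokens
            for _ in range(max(cfg.n_blocks - 1, 0)):
                self.upsamplers.append(TokenUpsample(n, rng))
                n *= 2

    def forward(self, tokens: Tensor) -> Tensor:
        x = tokens
        for i, block in enumerate(self.blocks):
            x = block(x)
            if self.upsamplers and i < len(self.upsamplers):
                x = self.upsamplers[i](x)
        return x

    def attention_maps(self) -> list[np.ndarray]:
        """Per-block (heads, N, N) attention weights from the last forward."""
        return [b.attn.last_attention for b in self.blocks]


def flatten_tokens(tokens) -> np.ndarray | Tensor:
    """Row-major flattening of the T x D token matrix to length T*D."""
    if isinstance(tokens, Tensor):
        return tokens.reshape(tokens.size)
    return np.asarray(tokens, dtype=float).reshape(-1)
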