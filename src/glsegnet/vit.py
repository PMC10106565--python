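"""Vision-transformer bottleneck.

The deepest encoder map (scale 16) is split into P x P patches, each patch is
linearly embedded and given a learned positional embedding, and the token
sequence passes through pre-norm transformer layers

    m' = MSA(LN(m_{l-1})) + m_{l-1}
    m  = MLP(LN(m'))      + m'

with scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V split across
heads.  Tokens are finally normalized, reshaped back onto the spatial grid and
projected to the encoder channel count by a 1x1 convolution, so the bottleneck
acts as a global semantic filter that preserves the feature-map geometry.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import ViTConfig
from .exceptions import ConfigurationError
from .nn import Conv2d, LayerNorm, Linear, Module, ModuleList, Parameter


def attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes."""
    q = q if isinstance(q, Tensor) else Tensor(q)
    k = k if isinstance(k, Tensor) else Tensor(k)
    v = v if isinstance(v, Tensor) else Tensor(v)
    if q.shape[-1] != k.shape[-1]:
        raise ConfigurationError(
            f"query dim {q.shape[-1]} != key dim {k.shape[-1]}")
    if k.shape[-2] != v.shape[-2]:
        raise ConfigurationError(
            f"key count {k.shape[-2]} != value count {v.shape[-2]}")
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    return ag.softmax(scores) @ v


class MultiHeadSelfAttention(Module):
    """n parallel attention heads, concatenated and mixed by W^O."""

    def __init__(self, dim: int, n_heads: int, *, rng, dtype=np.float32):
        super().__init__()
        if dim % n_heads:
            raise ConfigurationError(f"dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.wq = Linear(dim, dim, rng=rng, dtype=dtype)
        self.wk = Linear(dim, dim, rng=rng, dtype=dtype)
        self.wv = Linear(dim, dim, rng=rng, dtype=dtype)
        self.wo = Linear(dim, dim, rng=rng, dtype=dtype)

    def _split(self, t: Tensor) -> Tensor:
        B, N, K = t.shape
        return t.reshape(B, N, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        B, N, K = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        heads = attention(q, k, v)                       # (B, h, N, d)
        merged = heads.transpose(0, 2, 1, 3).reshape(B, N, K)
        return self.wo(merged)


class MLP(Module):
    """Two linear layers with a ReLU: max(0, X W1 + b1) W2 + b2."""

    def __init__(self, dim: int, hidden: int, *, rng, dtype=np.float32):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerLayer(Module):
    def __init__(self, dim: int, mlp_dim: int, n_heads: int, *, rng,
                 dtype=np.float32):
        super().__init__()
        self.ln1 = LayerNorm(dim, dtype=dtype)
        self.msa = MultiHeadSelfAttention(dim, n_heads, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.mlp = MLP(dim, mlp_dim, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = self.msa(self.ln1(x)) + x
        return self.mlp(self.ln2(x)) + x


class PatchEmbed(Module):
    """Flatten P x P x C patches, embed linearly, add positional embedding.

    The positional embedding is learned for a reference grid and bilinearly
    resized when the model is run at another input size.
    """

    def __init__(self, in_channels: int, patch_size: int, dim: int,
                 ref_grid: tuple[int, int], *, rng, dtype=np.float32):
        super().__init__()
        self.patch_size = patch_size
        self.in_channels = in_channels
        self.proj = Linear(patch_size * patch_size * in_channels, dim,
                           rng=rng, dtype=dtype)
        self.ref_grid = ref_grid
        self.pos = Parameter(np.zeros((ref_grid[0] * ref_grid[1], dim), dtype=dtype))

    def tokens_grid(self, h: int, w: int) -> tuple[int, int]:
        P = self.patch_size
        if h % P or w % P:
            raise ConfigurationError(
                f"feature map {h}x{w} not divisible by patch size {P}")
        return h // P, w // P

    def forward(self, x: Tensor) -> Tensor:
        B, C, h, w = x.shape
        P = self.patch_size
        gh, gw = self.tokens_grid(h, w)
        # (B,C,gh,P,gw,P) -> (B,gh,gw,P,P,C) -> (B, N, P*P*C)
        patches = (x.reshape(B, C, gh, P, gw, P)
                   .transpose(0, 2, 4, 3, 5, 1)
                   .reshape(B, gh * gw, P * P * C))
        tokens = self.proj(patches)
        pos = self.pos
        if (gh, gw) != self.ref_grid:
            rg = self.ref_grid
            pos4 = pos.reshape(1, rg[0], rg[1], -1).transpose(0, 3, 1, 2)
            pos4 = ag.upsample_bilinear(pos4, (gh, gw))
            pos = pos4.transpose(0, 2, 3, 1).reshape(gh * gw, tokens.shape[-1])
        return tokens + pos


class ViTBottleneck(Module):
    """Patch embedding, stacked transformer layers, projection back to a map."""

    def __init__(self, in_channels: int, cfg: ViTConfig, ref_size: int, *, rng,
                 dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        grid = ref_size // cfg.patch_size
        self.embed = PatchEmbed(in_channels, cfg.patch_size, cfg.hidden_dim,
                                (grid, grid), rng=rng, dtype=dtype)
        self.layers = ModuleList(
            TransformerLayer(cfg.hidden_dim, cfg.mlp_dim, cfg.n_heads, rng=rng,
                             dtype=dtype)
            for _ in range(cfg.n_layers))
        self.norm = LayerNorm(cfg.hidden_dim, dtype=dtype)
        self.out_proj = Conv2d(cfg.hidden_dim, in_channels, 1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, C, h, w = x.shape
        gh, gw = self.embed.tokens_grid(h, w)
        tokens = self.embed(x)
        for layer in self.layers:
            tokens = layer(tokens)
        tokens = self.norm(tokens)
        # patch_size > 1 would need an upsampling head; with the default P=1
        # the token grid is the feature grid itself.
        grid = tokens.reshape(B, gh, gw, self.cfg.hidden_dim).transpose(0, 3, 1, 2)
        if (gh, gw) != (h, w):
            grid = ag.upsample_bilinear(grid, (h, w))
        return self.out_proj(grid)
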