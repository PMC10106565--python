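"""Attention-enhanced decoder and full model assembly.

Each decoder stage summarizes its skip bundle with a 3x3 convolution, gates it
with a single-channel sigmoid signal computed from the coarser decoder feature
(attention gate, AG), concatenates the gated skip with the 2x-upsampled
decoder feature, and fuses with a 3x3 convolution:

    Y = Conv3x3([AG(X, C); UP(X)])

After the last gated stage (scale 2) a final 2x upsample and a 7x7
convolution + sigmoid produce the per-pixel foreground probability map.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor, no_grad
from .config import ModelConfig
from .encoder import ContextRichEncoder
from .exceptions import ShapeError
from .nn import Conv2d, ConvBNReLU, Module, ModuleList
from .vit import ViTBottleneck


class AttentionGate(Module):
    """AG(X, C) = sigmoid(psi(relu(Wx X + Wc C))) * C with a 1-channel gate."""

    def __init__(self, x_channels: int, c_channels: int, *, rng, dtype=np.float32):
        super().__init__()
        inter = max(c_channels // 2, 1)
        self.wx = Conv2d(x_channels, inter, 1, rng=rng, dtype=dtype)
        self.wc = Conv2d(c_channels, inter, 1, rng=rng, dtype=dtype)
        self.psi = Conv2d(inter, 1, 1, rng=rng, dtype=dtype)

    def gate(self, x: Tensor, c: Tensor) -> Tensor:
        if x.shape[2:] != c.shape[2:]:
            raise ShapeError(
                f"attention gate inputs disagree spatially: {x.shape[2:]} vs "
                f"{c.shape[2:]}")
        return self.psi((self.wx(x) + self.wc(c)).relu()).sigmoid()

    def forward(self, x: Tensor, c: Tensor) -> Tensor:
        return self.gate(x, c) * c


class DecoderStage(Module):
    """One cascaded-upsampling step consuming a summarized skip."""

    def __init__(self, in_channels: int, skip_channels: int, width: int,
                 use_gate: bool, *, rng, dtype=np.float32):
        super().__init__()
        self.summarize = ConvBNReLU(skip_channels, width, 3, padding=1, rng=rng,
                                    dtype=dtype)
        self.gate = AttentionGate(in_channels, width, rng=rng, dtype=dtype) \
            if use_gate else None
        self.fuse = ConvBNReLU(in_channels + width, width, 3, padding=1, rng=rng,
                               dtype=dtype)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = ag.upsample_bilinear(x, (skip.shape[2], skip.shape[3]))
        c = self.summarize(skip)
        gated = self.gate(up, c) if self.gate is not None else c
        return self.fuse(ag.concat([gated, up], axis=1))


class OutputHead(Module):
    """7x7 convolution to one channel followed by a sigmoid."""

    def __init__(self, in_channels: int, *, rng, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_channels, 1, 7, padding=3, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x).sigmoid()


class GLSegNet(Module):
    """Global-local segmentation network: context-rich encoder, transformer
    bottleneck, attention-gated cascaded-upsampling decoder."""

    def __init__(self, cfg: ModelConfig, *, rng=None, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.encoder = ContextRichEncoder(cfg, rng=rng, dtype=dtype)
        c4 = cfg.encoder_channels[3]
        if cfg.use_vit:
            self.vit = ViTBottleneck(c4, cfg.vit, ref_size=cfg.image_size // 16,
                                     rng=rng, dtype=dtype)
        else:
            self.vit = None
        s1, s2, s3 = self.encoder.skip_channels
        w8, w4, w2 = cfg.decoder_widths
        ag_on = cfg.use_attention_gate
        self.stage3 = DecoderStage(c4, s3, w8, ag_on, rng=rng, dtype=dtype)
        self.stage2 = DecoderStage(w8, s2, w4, ag_on, rng=rng, dtype=dtype)
        self.stage1 = DecoderStage(w4, s1, w2, ag_on, rng=rng, dtype=dtype)
        self.head = OutputHead(w2, rng=rng, dtype=dtype)
        self._dtype = dtype

    def forward(self, img, return_intermediates: bool = False):
        img = img if isinstance(img, Tensor) else Tensor(np.asarray(img, self._dtype))
        if img.dtype != self._dtype:
            img = Tensor(img.data.astype(self._dtype)) if not img.requires_grad else img
        H, W = img.shape[2], img.shape[3]
        f4, skips = self.encoder(img)
        bottleneck = self.vit(f4.values) if self.vit is not None else f4.values
        d3 = self.stage3(bottleneck, skips[2].values)   # scale 8
        d2 = self.stage2(d3, skips[1].values)           # scale 4
        d1 = self.stage1(d2, skips[0].values)           # scale 2
        full = ag.upsample_bilinear(d1, (H, W))
        mask = self.head(full)
        if return_intermediates:
            inter = {
                "level4": f4.values.shape,
                "skip1": skips[0].values.shape,
                "skip2": skips[1].values.shape,
                "skip3": skips[2].values.shape,
                "bottleneck": bottleneck.shape,
                "d3": d3.shape, "d2": d2.shape, "d1": d1.shape,
            }
            return mask, inter
        return mask

    def predict_proba(self, img) -> np.ndarray:
        """Inference forward pass (eval mode, no graph)."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(img).data
        finally:
            if was_training:
                self.train()
        return out

    def predict_mask(self, img, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(img) >= threshold).astype(np.uint8)


def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> GLSegNet:
    return GLSegNet(cfg, rng=np.random.default_rng(seed), dtype=dtype)
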