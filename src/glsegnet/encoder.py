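"""Context-rich residual encoder.

Four encoder layers halve the spatial size and double the channel count at
each step (schedule ``c, 2c, 4c, 8c`` at scales 2, 4, 8, 16).  The skip
connections are enriched before decoding:

* **MSC** — four parallel atrous (dilated) 3x3 convolutions with different
  rates widen the receptive field without losing resolution; their
  concatenation is fused back to the input width by a 3x3 convolution.
* **MSP** — non-overlapping max pooling at sizes 2, 4, 8, 16, each branch
  projected to one channel by a 1x1 convolution and bilinearly upsampled back,
  yields a 4-channel pyramid-pooling summary.
* **Multi-scale feature fusion** — stride-2 atrous convolutions push shallow
  features down to the scales of layers 2 and 3, where they are concatenated
  into those skip connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import ModelConfig
from .exceptions import ConfigurationError, ShapeError
from .nn import Conv2d, ConvBNReLU, Module, ModuleList, BatchNorm2d


@dataclass
class FeatureMap:
    """A feature array at one pyramid level (scale = input size divisor)."""

    values: Tensor
    level: int
    scale: int


@dataclass
class SkipBundle:
    """Concatenated skip-connection features feeding one decoder stage."""

    level: int
    values: Tensor


@dataclass
class AtrousConvSpec:
    """Geometry of one atrous convolution; sizes may be int or (h, w)."""

    kernel_size: int | tuple[int, int]
    atrous_rate: int
    in_channels: int
    out_channels: int
    stride: int = 1
    padding: int | tuple[int, int] = 0

    def __post_init__(self):
        kh, kw = self.kernel_hw
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigurationError("kernel_size must be odd")
        if self.atrous_rate < 1:
            raise ConfigurationError(
                f"atrous rate must be positive, got {self.atrous_rate}")

    @property
    def kernel_hw(self) -> tuple[int, int]:
        k = self.kernel_size
        return tuple(k) if isinstance(k, (tuple, list)) else (k, k)


def atrous_conv(x, spec: AtrousConvSpec, weight, bias=None) -> Tensor:
    """Dilated cross-correlation y[i] = sum_l x[i + d*l] w[l].

    ``weight`` has shape (out_channels, in_channels, k, k); with rate d = 1
    this is an ordinary convolution.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    weight = weight if isinstance(weight, Tensor) else Tensor(weight)
    if x.shape[1] != spec.in_channels:
        raise ConfigurationError(
            f"input has {x.shape[1]} channels, spec expects {spec.in_channels}")
    if weight.shape != (spec.out_channels, spec.in_channels) + spec.kernel_hw:
        raise ConfigurationError(
            f"weight shape {weight.shape} does not match spec")
    return ag.conv2d(x, weight, bias, stride=spec.stride,
                     padding=spec.padding, dilation=spec.atrous_rate)


class ResidualBlock(Module):
    """Two 3x3 convolutions with identity (or 1x1 projection) shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 *, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, padding=1,
                            rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1,
                            rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        if in_channels != out_channels or stride != 1:
            self.proj = Conv2d(in_channels, out_channels, 1, stride=stride,
                               bias=False, rng=rng, dtype=dtype)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        identity = x if self.proj is None else self.proj(x)
        return (h + identity).relu()


class MSCModule(Module):
    """Multi-Scale Convolution: parallel atrous branches, fused to input width."""

    def __init__(self, channels: int, rates=(1, 2, 4, 8), *, rng, dtype=np.float32):
        super().__init__()
        self.rates = tuple(rates)
        self.branches = ModuleList(
            ConvBNReLU(channels, channels, 3, padding=r, dilation=r, rng=rng,
                       dtype=dtype)
            for r in self.rates)
        self.fuse = ConvBNReLU(channels * len(self.rates), channels, 3, padding=1,
                               rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        need = 2 * max(self.rates) + 1
        if min(h, w) < need:
            raise ConfigurationError(
                f"MSC input {h}x{w} too small for atrous rate {max(self.rates)} "
                f"(needs at least {need})")
        return self.fuse(ag.concat([b(x) for b in self.branches], axis=1))


class MSPModule(Module):
    """Multi-Scale Pooling: max pool at several sizes, 1x1-project each branch
    to one channel, upsample back, concatenate."""

    def __init__(self, channels: int, sizes=(2, 4, 8, 16), *, rng, dtype=np.float32):
        super().__init__()
        self.sizes = tuple(sizes)
        self.convs = ModuleList(
            Conv2d(channels, 1, 1, rng=rng, dtype=dtype) for _ in self.sizes)

    @property
    def out_channels(self) -> int:
        return len(self.sizes)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        for s in self.sizes:
            if h % s or w % s:
                raise ConfigurationError(
                    f"MSP input {h}x{w} not divisible by pool size {s}")
        outs = []
        for s, conv in zip(self.sizes, self.convs):
            pooled = conv(ag.maxpool2d(x, s))
            outs.append(ag.upsample_bilinear(pooled, (h, w)))
        return ag.concat(outs, axis=1)


class DownsampleBranch(Module):
    """Stride-2 atrous convolution(s) taking a shallow map to a deeper scale."""

    def __init__(self, in_channels: int, out_channels: int, hops: int,
                 rates=(2, 4), *, rng, dtype=np.float32):
        super().__init__()
        convs = []
        cin = in_channels
        for i in range(hops):
            r = rates[min(i, len(rates) - 1)]
            convs.append(ConvBNReLU(cin, out_channels, 3, stride=2, padding=r,
                                    dilation=r, rng=rng, dtype=dtype))
            cin = out_channels
        self.convs = ModuleList(convs)

    def forward(self, x: Tensor) -> Tensor:
        for c in self.convs:
            x = c(x)
        return x


class ContextRichEncoder(Module):
    """Residual encoder with MSC/MSP enrichment and cross-level fusion.

    ``forward`` returns the deepest feature map (scale 16) and the three skip
    bundles at scales 2, 4, 8.
    """

    def __init__(self, cfg: ModelConfig, *, rng, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.encoder_channels
        self.stem = ConvBNReLU(cfg.in_channels, c1, 7, stride=2, padding=3,
                               rng=rng, dtype=dtype)
        self.layer1 = ResidualBlock(c1, c1, rng=rng, dtype=dtype)
        self.layer2 = ResidualBlock(c1, c2, stride=2, rng=rng, dtype=dtype)
        self.layer3 = ResidualBlock(c2, c3, stride=2, rng=rng, dtype=dtype)
        self.layer4 = ResidualBlock(c3, c4, stride=2, rng=rng, dtype=dtype)

        layer_ch = {1: c1, 2: c2, 3: c3}
        self.enriched = tuple(cfg.context_rich_layers) if cfg.use_context_rich else ()
        self.msc = ModuleList()
        self.msp = ModuleList()
        self._extra = {1: 0, 2: 0, 3: 0}
        for lvl in self.enriched:
            ch = layer_ch[lvl]
            self.msc.append(MSCModule(ch, cfg.msc_rates, rng=rng, dtype=dtype))
            self.msp.append(MSPModule(ch, cfg.msp_sizes, rng=rng, dtype=dtype))
            if cfg.context_rich_mode == "parallel":
                self._extra[lvl] = ch + len(cfg.msp_sizes)
            else:  # serial: MSP applied to the MSC output
                self._extra[lvl] = len(cfg.msp_sizes)

        self.fusion_on = cfg.use_context_rich and cfg.use_fusion
        if self.fusion_on:
            fb = cfg.fusion_branch_width
            self.l1_to4 = DownsampleBranch(c1, fb, hops=1, rates=(2,), rng=rng,
                                           dtype=dtype)
            self.l1_to8 = DownsampleBranch(c1, fb, hops=2, rates=(2, 4), rng=rng,
                                           dtype=dtype)
            self.l2_to8 = DownsampleBranch(c2, fb, hops=1, rates=(2,), rng=rng,
                                           dtype=dtype)
            self._fusion_extra = {2: fb, 3: 2 * fb}
        else:
            self._fusion_extra = {2: 0, 3: 0}

    @property
    def skip_channels(self) -> tuple[int, int, int]:
        """Channel counts of the skip bundles at levels 1, 2, 3."""
        c1, c2, c3, _ = self.cfg.encoder_channels
        base = {1: c1, 2: c2, 3: c3}
        return tuple(base[l] + self._extra[l] + self._fusion_extra.get(l, 0)
                     for l in (1, 2, 3))

    def _enrich(self, lvl: int, x: Tensor) -> list[Tensor]:
        if lvl not in self.enriched:
            return []
        i = self.enriched.index(lvl)
        if self.cfg.context_rich_mode == "parallel":
            return [self.msc[i](x), self.msp[i](x)]
        return [self.msp[i](self.msc[i](x))]

    def forward(self, img: Tensor) -> tuple[FeatureMap, list[SkipBundle]]:
        H, W = img.shape[2], img.shape[3]
        if H % 16 or W % 16:
            raise ShapeError(f"input size {H}x{W} must be divisible by 16")
        f1 = self.layer1(self.stem(img))        # c1 @ H/2
        f2 = self.layer2(f1)                    # c2 @ H/4
        f3 = self.layer3(f2)                    # c3 @ H/8
        f4 = self.layer4(f3)                    # c4 @ H/16

        skip1_parts = [f1] + self._enrich(1, f1)
        skip2_parts = [f2] + self._enrich(2, f2)
        skip3_parts = [f3] + self._enrich(3, f3)
        if self.fusion_on:
            b14 = self.l1_to4(f1)
            b18 = self.l1_to8(f1)
            b28 = self.l2_to8(f2)
            for name, t, ref in (("l1->4", b14, f2), ("l1->8", b18, f3),
                                 ("l2->8", b28, f3)):
                if t.shape[2:] != ref.shape[2:]:
                    raise ShapeError(
                        f"fusion branch {name} produced {t.shape[2:]}, "
                        f"expected {ref.shape[2:]}")
            skip2_parts.append(b14)
            skip3_parts.extend([b18, b28])

        skips = [
            SkipBundle(1, ag.concat(skip1_parts, axis=1) if len(skip1_parts) > 1
                       else skip1_parts[0]),
            SkipBundle(2, ag.concat(skip2_parts, axis=1) if len(skip2_parts) > 1
                       else skip2_parts[0]),
            SkipBundle(3, ag.concat(skip3_parts, axis=1) if len(skip3_parts) > 1
                       else skip3_parts[0]),
        ]
        return FeatureMap(f4, level=4, scale=16), skips
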