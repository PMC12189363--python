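"""The segmentation network.

Architecture: a split-attention residual encoder (ResNeSt-style, 50-layer
deep-stem variant by default), a nested dense-skip decoder (UNet++-style
triangular grid of convolutional nodes), channel squeeze-excitation (cSE)
attention on the decoder path, and a 3-class segmentation head
(background / left ventricle / myocardium).

Encoder variants
----------------
``splitattn-50-deepstem``
    50-layer bottleneck network with split-attention 3x3 convolutions
    (radix groups recombined through a radix-softmax), deep 3-conv stem,
    and average-pool downsampling on both residual branches.  Stage
    channels 3, 64, 256, 512, 1024, 2048 at strides 1..32.
``resnet-34``
    Standard 34-layer basic-block residual network (ablation baseline).
``plain``
    A small strided double-conv encoder for fast tests and ablations.

The decoder follows the canonical UNet++ channel bookkeeping: dense grid
nodes carry the encoder skip width, the first row carries the configured
decoder widths, every node is two 3x3 conv+BN+ReLU with an attention gate on
its concatenated input and on its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import Tensor
from . import nn as N
from .nn import tensor as T
from .errors import ConfigError, StructuralError

ENCODER_VARIANTS = ("splitattn-50-deepstem", "resnet-34", "plain")
ATTENTION_VARIANTS = ("cse", "scse", "none")


@dataclass
class NetworkConfig:
    """Configuration of the segmentation network.

    ``decoder_channels`` are the widths of the first-row decoder nodes from
    deepest to shallowest; ``radix``/``cardinality`` parameterize the
    split-attention blocks; ``decoder_attention`` selects the gate placed on
    every decoder node (``cse`` is the proposed configuration, ``scse`` and
    ``none`` are ablations).  ``pretrained`` accepts a checkpoint path for
    encoder initialization; no weights ship with the package and the default
    is random He-normal initialization.
    """

    encoder_variant: str = "splitattn-50-deepstem"
    radix: int = 2
    cardinality: int = 1
    base_width: int = 64
    decoder_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    decoder_attention: str = "cse"
    cse_reduction: int = 16
    n_classes: int = 3
    in_channels: int = 3
    plain_width: int = 32
    pretrained: bool = False

    def __post_init__(self):
        if self.encoder_variant not in ENCODER_VARIANTS:
            raise ConfigError(f"unknown encoder variant "
                              f"{self.encoder_variant!r}; "
                              f"choose from {ENCODER_VARIANTS}")
        if self.decoder_attention not in ATTENTION_VARIANTS:
            raise ConfigError(f"unknown decoder attention "
                              f"{self.decoder_attention!r}")
        if len(self.decoder_channels) != 5:
            raise ConfigError("decoder_channels must list 5 widths "
                              "(one per pyramid level)")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decoder_channels"] = list(self.decoder_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["decoder_channels"] = tuple(d["decoder_channels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# attention gates
# ---------------------------------------------------------------------------

class CSEBlock(nn.Module):
    """Channel squeeze-excitation gate.

    Global average pooling over H x W, a two-layer 1x1-conv bottleneck
    (ReLU then sigmoid), and an elementwise rescaling of the input by the
    resulting per-channel factors in (0, 1).
    """

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        mid = max(channels // reduction, 1)
        self.fc1 = nn.Conv2d(channels, mid, 1)
        self.fc2 = nn.Conv2d(mid, channels, 1)
        # start the narrow bottleneck slightly positive so no ReLU unit is
        # dead at initialization (the gate still opens near 0.5)
        self.fc1.bias.data[...] = 0.1

    def gate(self, x: Tensor) -> Tensor:
        s = N.global_avgpool(x)
        s = T.relu(self.fc1(s))
        return T.sigmoid(self.fc2(s))

    def forward(self, x: Tensor) -> Tensor:
        return T.mul(x, self.gate(x))


class SCSEBlock(nn.Module):
    """Concurrent spatial and channel squeeze-excitation.

    The channel gate is `CSEBlock`; the spatial gate is a 1x1 convolution to
    a single sigmoid plane.  The two gated maps are combined elementwise by
    maximum.
    """

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        self.cse = CSEBlock(channels, reduction)
        self.spatial = nn.Conv2d(channels, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        xc = self.cse(x)
        xs = T.mul(x, T.sigmoid(self.spatial(x)))
        return T.maximum(xc, xs)


def make_attention(kind: str, channels: int, reduction: int = 16) -> nn.Module:
    if kind == "cse":
        return CSEBlock(channels, reduction)
    if kind == "scse":
        return SCSEBlock(channels, reduction)
    if kind == "none":
        return nn.Identity()
    raise ConfigError(f"unknown attention kind {kind!r}")


# ---------------------------------------------------------------------------
# split-attention convolution
# ---------------------------------------------------------------------------

class SplitAttentionConv2d(nn.Module):
    """3x3 split-attention convolution.

    Channels are expanded to ``radix`` splits per cardinal group by a grouped
    convolution; the splits are summed, globally pooled, passed through a
    two-layer bottleneck, and a radix-softmax produces per-channel weights
    (summing to 1 across splits) that recombine the splits.  With radix 1 the
    gate degenerates to a sigmoid (plain squeeze-excitation).
    """

    def __init__(self, in_channels: int, channels: int, radix: int = 2,
                 cardinality: int = 1, reduction_factor: int = 4):
        super().__init__()
        if channels % (radix * cardinality):
            raise ConfigError(
                f"channels={channels} not divisible by "
                f"radix*cardinality={radix * cardinality}")
        self.radix, self.cardinality, self.channels = radix, cardinality, channels
        inter = max(channels * radix // reduction_factor, 32)
        self.conv = nn.Conv2d(in_channels, channels * radix, 3, padding=1,
                              groups=cardinality * radix, bias=False)
        self.bn0 = nn.BatchNorm2d(channels * radix)
        self.fc1 = nn.Conv2d(channels, inter, 1, groups=cardinality)
        self.bn1 = nn.BatchNorm2d(inter)
        self.fc2 = nn.Conv2d(inter, channels * radix, 1, groups=cardinality)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        r, k, ch = self.radix, self.cardinality, self.channels
        x = T.relu(self.bn0(self.conv(x)))
        n, _, h, w = x.shape
        if r > 1:
            xs = T.reshape(x, (n, r, ch, h, w))
            gap = T.tsum(xs, axis=1)
        else:
            gap = x
        gap = N.global_avgpool(gap)
        gap = T.relu(self.bn1(self.fc1(gap)))
        att = self.fc2(gap)                       # (n, ch*r, 1, 1)
        if r > 1:
            # channel layout of fc2 output is (cardinality, radix, ch/k);
            # softmax runs across the radix axis
            att = T.reshape(att, (n, k, r, ch // k))
            att = T.transpose(att, (0, 2, 1, 3))
            att = T.softmax(att, axis=1)
            self.last_attention = att.data.reshape(n, r, ch)
            att = T.reshape(att, (n, r, ch, 1, 1))
            out = T.tsum(T.mul(xs, att), axis=1)
        else:
            att = T.sigmoid(att)
            self.last_attention = att.data.reshape(n, 1, ch)
            out = T.mul(x, att)
        return out


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class SplitAttentionBottleneck(nn.Module):
    """ResNeSt-style bottleneck: 1x1 reduce, split-attention 3x3, 1x1 expand.

    Stride is realized by a 3x3 average pool after the split-attention
    convolution; the shortcut downsamples by average pooling before its 1x1
    projection (the "deep-stem / avg-down" design).
    """

    expansion = 4

    def __init__(self, in_channels: int, planes: int, stride: int,
                 radix: int, cardinality: int, base_width: int):
        super().__init__()
        group_width = int(planes * (base_width / 64.0)) * cardinality
        self.conv1 = nn.Conv2d(in_channels, group_width, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(group_width)
        self.conv2 = SplitAttentionConv2d(group_width, group_width, radix,
                                          cardinality)
        self.avd = nn.AvgPool2d(3, stride, 1) if stride > 1 else nn.Identity()
        self.conv3 = nn.Conv2d(group_width, planes * self.expansion, 1,
                               bias=False)
        self.bn3 = nn.BatchNorm2d(planes * self.expansion)
        if stride > 1 or in_channels != planes * self.expansion:
            down = []
            if stride > 1:
                down.append(nn.AvgPool2d(stride, stride))
            down += [nn.Conv2d(in_channels, planes * self.expansion, 1,
                               bias=False),
                     nn.BatchNorm2d(planes * self.expansion)]
            self.downsample = nn.Sequential(*down)
        else:
            self.downsample = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = T.relu(self.bn1(self.conv1(x)))
        out = self.conv2(out)
        out = self.avd(out)
        out = self.bn3(self.conv3(out))
        return T.relu(T.add(out, self.downsample(x)))


class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_channels: int, planes: int, stride: int):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, planes, 3, stride, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, 1, 1, bias=False)
        self.bn2 = nn.BatchNorm2d(planes)
        if stride > 1 or in_channels != planes:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_channels, planes, 1, stride, bias=False),
                nn.BatchNorm2d(planes))
        else:
            self.downsample = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        out = T.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return T.relu(T.add(out, self.downsample(x)))


class _StagedEncoder(nn.Module):
    """Base for encoders producing 6 feature maps at strides 1..32."""

    out_channels: tuple[int, ...]

    def forward(self, x: Tensor) -> list[Tensor]:  # pragma: no cover
        raise NotImplementedError


class SplitAttentionEncoder(_StagedEncoder):
    """50-layer split-attention encoder with deep stem (stage layout 3-4-6-3)."""

    def __init__(self, in_channels: int = 3, radix: int = 2,
                 cardinality: int = 1, base_width: int = 64,
                 stem_width: int = 32):
        super().__init__()
        self.stem = nn.Sequential(
            nn.conv_bn_relu(in_channels, stem_width, 3, stride=2),
            nn.conv_bn_relu(stem_width, stem_width, 3),
            nn.conv_bn_relu(stem_width, stem_width * 2, 3))
        self.pool = nn.MaxPool2d(3, 2, 1)
        layers = (3, 4, 6, 3)
        planes = (64, 128, 256, 512)
        strides = (1, 2, 2, 2)
        in_ch = stem_width * 2
        self.stages = []
        for i, (nblocks, p, s) in enumerate(zip(layers, planes, strides)):
            blocks = []
            for j in range(nblocks):
                blocks.append(SplitAttentionBottleneck(
                    in_ch, p, s if j == 0 else 1, radix, cardinality,
                    base_width))
                in_ch = p * SplitAttentionBottleneck.expansion
            stage = nn.Sequential(*blocks)
            self.stages.append(stage)
            self._modules[f"layer{i + 1}"] = stage
        self.out_channels = (in_channels, stem_width * 2, 256, 512, 1024, 2048)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = [x]
        x = self.stem(x)
        feats.append(x)
        x = self.pool(x)
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


class ResNet34Encoder(_StagedEncoder):
    def __init__(self, in_channels: int = 3):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, 64, 7, 2, 3, bias=False)
        self.bn1 = nn.BatchNorm2d(64)
        self.pool = nn.MaxPool2d(3, 2, 1)
        layers = (3, 4, 6, 3)
        planes = (64, 128, 256, 512)
        strides = (1, 2, 2, 2)
        in_ch = 64
        self.stages = []
        for i, (nblocks, p, s) in enumerate(zip(layers, planes, strides)):
            blocks = []
            for j in range(nblocks):
                blocks.append(BasicBlock(in_ch, p, s if j == 0 else 1))
                in_ch = p
            stage = nn.Sequential(*blocks)
            self.stages.append(stage)
            self._modules[f"layer{i + 1}"] = stage
        self.out_channels = (in_channels, 64, 64, 128, 256, 512)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = [x]
        x = T.relu(self.bn1(self.conv1(x)))
        feats.append(x)
        x = self.pool(x)
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


class PlainEncoder(_StagedEncoder):
    """Small strided double-conv encoder (no residual connections)."""

    def __init__(self, in_channels: int = 3, width: int = 32):
        super().__init__()
        chans = (width, width * 2, width * 4, width * 8, width * 16)
        in_ch = in_channels
        self.stages = []
        for i, c in enumerate(chans):
            stage = nn.Sequential(nn.conv_bn_relu(in_ch, c, 3, stride=2),
                                  nn.conv_bn_relu(c, c, 3))
            self.stages.append(stage)
            self._modules[f"stage{i}"] = stage
            in_ch = c
        self.out_channels = (in_channels,) + chans

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = [x]
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


def build_encoder(cfg: NetworkConfig) -> _StagedEncoder:
    """Construct the encoder named by ``cfg.encoder_variant``."""
    if cfg.encoder_variant == "splitattn-50-deepstem":
        return SplitAttentionEncoder(cfg.in_channels, cfg.radix,
                                     cfg.cardinality, cfg.base_width)
    if cfg.encoder_variant == "resnet-34":
        return ResNet34Encoder(cfg.in_channels)
    if cfg.encoder_variant == "plain":
        return PlainEncoder(cfg.in_channels, cfg.plain_width)
    raise ConfigError(f"unknown encoder variant {cfg.encoder_variant!r}")


# ---------------------------------------------------------------------------
# nested dense-skip decoder
# ---------------------------------------------------------------------------

class DecoderBlock(nn.Module):
    """One decoder node: upsample x2, concat skips, attention, 2x conv."""

    def __init__(self, in_channels: int, skip_channels: int,
                 out_channels: int, attention: str, reduction: int):
        super().__init__()
        self.attention1 = make_attention(attention, in_channels + skip_channels,
                                         reduction)
        self.conv1 = nn.conv_bn_relu(in_channels + skip_channels, out_channels)
        self.conv2 = nn.conv_bn_relu(out_channels, out_channels)
        self.attention2 = make_attention(attention, out_channels, reduction)

    def forward(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        x = N.upsample_bilinear(x, 2)
        if skips:
            for s in skips:
                if s.shape[2:] != x.shape[2:]:
                    raise StructuralError(
                        f"skip spatial size {s.shape[2:]} does not match "
                        f"upsampled input {x.shape[2:]}")
            x = T.concat([x] + skips, axis=1)
        x = self.attention1(x)
        x = self.conv2(self.conv1(x))
        return self.attention2(x)


class NestedDecoder(nn.Module):
    """UNet++-style triangular grid of decoder nodes.

    Nodes are keyed ``x_{d}_{l}``: ``l`` indexes the pyramid level of the
    node's output (0 = deepest decoded level) and ``d`` the skip-path
    position.  Node outputs are retained in ``last_nodes`` after each forward
    for introspection and Grad-CAM.
    """

    def __init__(self, encoder_channels: tuple[int, ...],
                 decoder_channels: tuple[int, ...], attention: str = "cse",
                 reduction: int = 16):
        super().__init__()
        enc = list(encoder_channels[1:])[::-1]          # deepest first
        depth = len(enc) - 1                            # 4 grid columns
        in_ch = [enc[0]] + list(decoder_channels[:-1])
        skip_ch = enc[1:] + [0]
        out_ch = list(decoder_channels)
        self.depth = depth
        self.blocks: dict[str, DecoderBlock] = {}

        def add_block(name, i, s, o):
            blk = DecoderBlock(i, s, o, attention, reduction)
            self.blocks[name] = blk
            self._modules[name] = blk

        for l in range(depth):
            for d in range(l + 1):
                if d == 0:
                    add_block(f"x_0_{l}", in_ch[l], skip_ch[l] * (l + 1),
                              out_ch[l])
                else:
                    add_block(f"x_{d}_{l}", skip_ch[l - 1],
                              skip_ch[l] * (l + 1 - d), skip_ch[l])
        add_block(f"x_0_{depth}", in_ch[depth], 0, out_ch[depth])
        self.out_channels = out_ch[-1]
        self.last_nodes: dict[str, Tensor] = {}

    def xgrid_node_count(self) -> int:
        """Encoder stages plus dense decoder nodes of the triangular grid."""
        return (self.depth + 1) + sum(range(1, self.depth + 1))

    def forward(self, features: list[Tensor]) -> Tensor:
        f = features[1:][::-1]
        X: dict[tuple[int, int], Tensor] = {}
        for d in range(self.depth):
            X[(d, d)] = self.blocks[f"x_{d}_{d}"](f[d], [f[d + 1]])
        for off in range(1, self.depth):
            for d in range(self.depth - off):
                l = d + off
                skips = [X[(k, l)] for k in range(d + 1, l + 1)] + [f[l + 1]]
                X[(d, l)] = self.blocks[f"x_{d}_{l}"](X[(d, l - 1)], skips)
        X[(0, self.depth)] = self.blocks[f"x_0_{self.depth}"](
            X[(0, self.depth - 1)], [])
        self.last_nodes = {f"x_{d}_{l}": t for (d, l), t in X.items()}
        return X[(0, self.depth)]


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class SegmentationNet(nn.Module):
    """Encoder + nested decoder + 3x3 classification head."""

    def __init__(self, cfg: NetworkConfig | None = None):
        super().__init__()
        self.cfg = cfg or NetworkConfig()
        if self.cfg.pretrained:
            raise ConfigError(
                "no pretrained encoder weights ship with this package; "
                "initialize randomly and load a checkpoint instead")
        self.encoder = build_encoder(self.cfg)
        self.decoder = NestedDecoder(self.encoder.out_channels,
                                     self.cfg.decoder_channels,
                                     self.cfg.decoder_attention,
                                     self.cfg.cse_reduction)
        self.head = nn.Conv2d(self.cfg.decoder_channels[-1],
                              self.cfg.n_classes, 3, padding=1)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4:
            raise StructuralError(f"expected NCHW batch, got shape {x.shape}")
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise StructuralError(
                f"expected {self.cfg.in_channels} input channels, got {c}")
        if h % 32 or w % 32:
            raise StructuralError(
                f"input spatial size {h}x{w} must be divisible by 32")
        return self.head(self.decoder(self.encoder(x)))

    def predict_proba(self, x) -> np.ndarray:
        """Softmax class probabilities; graph-free, evaluation mode."""
        was_training = self.training
        self.eval()
        try:
            with T.no_grad():
                return T.softmax(self.forward(x), axis=1).data
        finally:
            self.train(was_training)

    def predict(self, x) -> np.ndarray:
        """Hard label masks via channel argmax."""
        return self.predict_proba(x).argmax(axis=1).astype(np.int64)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalar entries in the model."""
    return int(sum(p.data.size for p in model.parameters()))


def build_model(cfg: NetworkConfig | None = None,
                seed: int | None = None) -> SegmentationNet:
    """Build a `SegmentationNet`, optionally seeding weight initialization."""
    if seed is not None:
        nn.set_seed(seed)
    return SegmentationNet(cfg)
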