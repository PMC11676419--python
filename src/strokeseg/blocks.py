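"""Convolutional building blocks of the segmentation network.

The encoder/decoder is assembled from five primitives:

* **stem** - a single Conv3x3 -> BN -> ReLU lifting the one-channel MRI slice
  to ``stem_width`` feature channels without changing resolution.
* **dilated block** - three Conv3x3 -> BN -> ReLU layers whose dilation rate
  doubles layer to layer (2, 4, 8 by default), growing the receptive field to
  ``1 + 2 * sum(rates)`` pixels without extra parameters.
* **dense block** - DenseNet-style connectivity: each layer is
  BN -> ReLU -> Conv3x3 producing ``growth`` channels that are concatenated
  onto the running feature stack, so a block with L layers adds ``L * growth``
  channels to its input.
* **dilated dense block (DDB)** - the dilated stack followed by the dense
  block, so dense layers inherit the enlarged spatial context.
* **transition layer** - BN -> ReLU -> Conv1x1 channel compression (keep a
  ``compression`` fraction), then a strided Conv3x3 that halves both spatial
  dimensions.  Odd inputs are rejected so shapes stay exactly reproducible.
* **upsample block** - nearest-neighbour x2 followed by a Conv1x1 that halves
  the channel count.

Feature maps are NHWC tensors; every block preserves finiteness and the shape
contracts asserted in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class DDBConfig:
    """Knobs of one dilated dense block."""

    dilated_channels: int = 110
    dilation_rates: tuple[int, ...] = (2, 4, 8)
    dense_layers: int = 4
    growth: int = 17
    dropout: float = 0.2

    def __post_init__(self):
        if self.dilated_channels < 1:
            raise ValueError("dilated_channels must be >= 1")
        rates = tuple(self.dilation_rates)
        if not rates or any(r < 1 for r in rates):
            raise ValueError("dilation rates must all be >= 1")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dilation rates must be strictly increasing")
        if self.dense_layers < 1:
            raise ValueError("dense_layers must be >= 1")
        if self.growth < 1:
            raise ValueError("growth must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def receptive_field(self) -> int:
        """Support width of the dilated stack's unit-impulse response."""
        return 1 + 2 * sum(self.dilation_rates)

    def out_channels(self, _in_channels: int | None = None) -> int:
        return self.dilated_channels + self.dense_layers * self.growth


@dataclass(frozen=True)
class TransitionConfig:
    """Compression fraction and (fixed) spatial stride of a transition layer."""

    compression: float = 0.5
    stride: int = field(default=2)

    def __post_init__(self):
        if not 0.0 < self.compression <= 1.0:
            raise ValueError("compression must be in (0, 1]")
        if self.stride != 2:
            raise ValueError("transition stride is fixed at 2")


def _check_map(x: Tensor) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected NHWC feature map, got shape {x.shape}")


class StemBlock(nn.Module):
    """Conv3x3 -> BN -> ReLU on the single-modality input; resolution kept."""

    def __init__(self, stem_width: int, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        if in_channels != 1:
            raise ValueError(
                f"the stem expects a single-modality (1-channel) input, "
                f"got {in_channels} channels")
        self.conv = nn.Conv2d(1, stem_width, 3, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(stem_width)
        self.out_channels = stem_width

    def forward(self, x: Tensor) -> Tensor:
        _check_map(x)
        if x.shape[-1] != 1:
            raise ValueError(
                f"the stem expects a single-modality (1-channel) input, "
                f"got {x.shape[-1]} channels")
        return nn.relu(self.bn(self.conv(x)))


class DilatedBlock(nn.Module):
    """Stack of dilated Conv3x3 -> BN -> ReLU layers (rates 2, 4, 8)."""

    def __init__(self, in_channels: int, cfg: DDBConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.layers = nn.ModuleList()
        self.bns = nn.ModuleList()
        c = in_channels
        for rate in cfg.dilation_rates:
            self.layers.append(nn.Conv2d(c, cfg.dilated_channels, 3,
                                         dilation=rate, bias=False, rng=rng))
            self.bns.append(nn.BatchNorm2d(cfg.dilated_channels))
            c = cfg.dilated_channels
        self.out_channels = cfg.dilated_channels

    def forward(self, x: Tensor) -> Tensor:
        _check_map(x)
        for conv, bn in zip(self.layers, self.bns):
            x = nn.relu(bn(conv(x)))
        return x


class DenseBlock(nn.Module):
    """Densely connected BN -> ReLU -> Conv3x3(growth) layers.

    Layer i sees the concatenation of the block input and all previous layer
    outputs; the block emits ``in_channels + L * growth`` channels.
    """

    def __init__(self, in_channels: int, cfg: DDBConfig,
                 rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None):
        super().__init__()
        self.bns = nn.ModuleList()
        self.convs = nn.ModuleList()
        self.drops = nn.ModuleList()
        c = in_channels
        for _ in range(cfg.dense_layers):
            self.bns.append(nn.BatchNorm2d(c))
            self.convs.append(nn.Conv2d(c, cfg.growth, 3, bias=True, rng=rng))
            self.drops.append(nn.Dropout(cfg.dropout, rng=dropout_rng))
            c += cfg.growth
        self.out_channels = c

    def forward(self, x: Tensor) -> Tensor:
        _check_map(x)
        for bn, conv, drop in zip(self.bns, self.convs, self.drops):
            new = drop(conv(nn.relu(bn(x))))
            x = nn.concat([x, new], axis=-1)
        return x


class DilatedDenseBlock(nn.Module):
    """DDB = dilated block then dense block; resolution preserved."""

    def __init__(self, in_channels: int, cfg: DDBConfig,
                 rng: np.random.Generator,
                 dropout_rng: np.random.Generator | None = None,
                 use_dilated: bool = True):
        super().__init__()
        self.dilated = (DilatedBlock(in_channels, cfg, rng)
                        if use_dilated else None)
        dense_in = cfg.dilated_channels if use_dilated else in_channels
        self.dense = DenseBlock(dense_in, cfg, rng, dropout_rng)
        self.out_channels = self.dense.out_channels

    def forward(self, x: Tensor) -> Tensor:
        if self.dilated is not None:
            x = self.dilated(x)
        return self.dense(x)


class PlainBlock(nn.Module):
    """Classic U-Net double conv (Conv3x3 -> BN -> ReLU, twice).

    Used by the plain-U-Net ablation variant in place of the DDB.
    """

    def __init__(self, in_channels: int, width: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_channels, width, 3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.out_channels = width

    def forward(self, x: Tensor) -> Tensor:
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class TransitionLayer(nn.Module):
    """BN -> ReLU -> Conv1x1 (keep ``compression`` of channels) -> strided
    Conv3x3 halving height and width."""

    def __init__(self, in_channels: int, cfg: TransitionConfig,
                 rng: np.random.Generator):
        super().__init__()
        out = int(np.floor(cfg.compression * in_channels))
        if out < 1:
            raise ValueError("compression leaves no channels")
        self.bn = nn.BatchNorm2d(in_channels)
        self.compress = nn.Conv2d(in_channels, out, 1, bias=True, rng=rng)
        self.down = nn.Conv2d(out, out, 3, stride=cfg.stride, bias=True,
                              rng=rng)
        self.out_channels = out

    def forward(self, x: Tensor) -> Tensor:
        _check_map(x)
        _, h, w, _ = x.shape
        if h % 2 or w % 2:
            raise ValueError(
                f"transition layer requires even spatial dims, got {h}x{w}")
        x = nn.relu(self.bn(x))
        return self.down(self.compress(x))


class UpsampleBlock(nn.Module):
    """Nearest-neighbour x2 upsampling followed by a channel-halving Conv1x1."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        if in_channels < 2:
            raise ValueError("upsample block needs at least 2 channels")
        self.conv = nn.Conv2d(in_channels, in_channels // 2, 1, bias=True,
                              rng=rng)
        self.out_channels = in_channels // 2

    def forward(self, x: Tensor) -> Tensor:
        _check_map(x)
        return self.conv(nn.upsample_nearest2x(x))


# -- functional conveniences (single feature map in, single map out) --------

def _apply(block: nn.Module, x: np.ndarray) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError(f"expected an HxWxC feature map, got shape {arr.shape}")
    block.eval()
    with nn.no_grad():
        out = block(Tensor(arr[None]))
    return out.data[0]

def stem(x: np.ndarray, stem_width: int, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialised stem block to one feature map."""
    return _apply(StemBlock(stem_width, np.random.default_rng(seed)), x)

def dilated_block(x: np.ndarray, cfg: DDBConfig, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _apply(DilatedBlock(np.asarray(x).shape[-1], cfg, rng), x)

def dense_block(x: np.ndarray, cfg: DDBConfig, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _apply(DenseBlock(np.asarray(x).shape[-1], cfg, rng), x)

def ddb(x: np.ndarray, cfg: DDBConfig, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _apply(DilatedDenseBlock(np.asarray(x).shape[-1], cfg, rng), x)

def transition_layer(x: np.ndarray, cfg: TransitionConfig,
                     seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _apply(TransitionLayer(np.asarray(x).shape[-1], cfg, rng), x)

def upsample(x: np.ndarray, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return _apply(UpsampleBlock(np.asarray(x).shape[-1], rng), x)
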