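"""Model factory: the five ablation variants, weight init, parameter counts.

Topology (flagship)::

    stem -> [DDB -> transition] x2 -> DDB -> transition -> center DDB
         -> [upsample -> concat skip -> transformer -> DDB] x3
         -> Conv1x1 -> sigmoid

Three skip connections pair each encoder DDB output with the decoder stage
of equal resolution.  Variants toggle the dilated stack, the decoder
transformer blocks, or swap the DDB for a plain U-Net double conv:

====================================  ========  ============  ===========
variant                               dilated   transformer   block style
====================================  ========  ============  ===========
transformer_dil_denseunet             yes       yes           dense
transformer_denseunet                 no        yes           dense
dil_denseunet                         yes       no            dense
denseunet                             no        no            dense
transformer_unet                      no        yes           plain
====================================  ========  ============  ===========

The default widths are the calibrated schedule found by
``scripts/calibrate_widths.py``; with them the flagship variant counts
13,662,913 parameters (13,649,473 trainable + 13,440 batch-norm running
statistics), the reference budget of the architecture.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from . import nn
from .attention import TransformerBlock2d
from .blocks import (DDBConfig, DilatedDenseBlock, PlainBlock, StemBlock,
                     TransitionConfig, TransitionLayer, UpsampleBlock)
from .nn import Tensor

__all__ = [
    "VARIANTS", "ModelConfig", "ParamCount", "SegmentationModel",
    "build_model", "count_parameters", "bn_channel_sum", "he_normal_init",
    "binarize", "save_checkpoint", "load_checkpoint",
]

VARIANTS = {
    "transformer_dil_denseunet": dict(dilated=True, transformer=True,
                                      block="dense"),
    "transformer_denseunet": dict(dilated=False, transformer=True,
                                  block="dense"),
    "dil_denseunet": dict(dilated=True, transformer=False, block="dense"),
    "denseunet": dict(dilated=False, transformer=False, block="dense"),
    "transformer_unet": dict(dilated=False, transformer=True, block="plain"),
}


@dataclass(frozen=True)
class ModelConfig:
    """All architecture knobs, pinned so parameter counts are reproducible."""

    variant: str = "transformer_dil_denseunet"
    stem_width: int = 82
    dilated_channels: int = 110
    dilation_rates: tuple[int, ...] = (2, 4, 8)
    dense_layers: int = 4
    growth: int = 17
    compression: float = 0.5
    heads: int = 4
    embed_dim: int = 260
    ffn_dim: int = 4057
    patch_schedule: tuple[int, int, int] = (1, 2, 4)
    dropout: float = 0.2
    norm_placement: str = "post"
    input_channels: int = 1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from "
                f"{sorted(VARIANTS)}")
        for name in ("stem_width", "dilated_channels", "dense_layers",
                     "growth", "heads", "embed_dim", "ffn_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.input_channels != 1:
            raise ValueError("input is single-modality: input_channels must "
                             "be 1")
        if len(self.patch_schedule) != 3 or any(
                p < 1 for p in self.patch_schedule):
            raise ValueError("patch_schedule needs three positive entries")
        if self.embed_dim % self.heads:
            raise ValueError("heads must divide embed_dim")
        if self.embed_dim % 2:
            raise ValueError("embed_dim must be even (sinusoidal encoding)")
        # delegate the remaining range checks
        self.ddb_config()
        TransitionConfig(self.compression)

    def ddb_config(self) -> DDBConfig:
        return DDBConfig(self.dilated_channels, tuple(self.dilation_rates),
                         self.dense_layers, self.growth, self.dropout)

    @property
    def flags(self) -> dict:
        return VARIANTS[self.variant]

    def with_variant(self, variant: str) -> "ModelConfig":
        return replace(self, variant=variant)


@dataclass(frozen=True)
class ParamCount:
    total: int
    trainable: int
    non_trainable: int

    def __post_init__(self):
        if self.total != self.trainable + self.non_trainable:
            raise ValueError("total must equal trainable + non_trainable")

    def as_dict(self) -> dict:
        return asdict(self)


class SegmentationModel(nn.Module):
    """Encoder-decoder segmentation network built from a :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(np.random.SeedSequence(
            [seed, 0x5eed]))
        flags = config.flags
        ddb_cfg = config.ddb_config()
        trans_cfg = TransitionConfig(config.compression)
        plain_width = ddb_cfg.out_channels()

        def make_block(cin: int) -> nn.Module:
            if flags["block"] == "plain":
                return PlainBlock(cin, plain_width, rng)
            return DilatedDenseBlock(cin, ddb_cfg, rng, drop_rng,
                                     use_dilated=flags["dilated"])

        self.stem = StemBlock(config.stem_width, rng,
                              in_channels=config.input_channels)
        c = self.stem.out_channels

        self.enc_blocks = nn.ModuleList()
        self.transitions = nn.ModuleList()
        skip_channels = []
        for _ in range(3):
            blk = make_block(c)
            self.enc_blocks.append(blk)
            c = blk.out_channels
            skip_channels.append(c)
            tr = TransitionLayer(c, trans_cfg, rng)
            self.transitions.append(tr)
            c = tr.out_channels

        self.center = make_block(c)
        c = self.center.out_channels

        self.upsamples = nn.ModuleList()
        self.attn_blocks = nn.ModuleList() if flags["transformer"] else None
        self.dec_blocks = nn.ModuleList()
        for i, skip_c in enumerate(reversed(skip_channels)):
            up = UpsampleBlock(c, rng)
            self.upsamples.append(up)
            c = up.out_channels + skip_c
            if flags["transformer"]:
                self.attn_blocks.append(TransformerBlock2d(
                    c, config.patch_schedule[i], config.embed_dim,
                    config.heads, config.ffn_dim, rng,
                    config.norm_placement))
            blk = make_block(c)
            self.dec_blocks.append(blk)
            c = blk.out_channels

        self.head = nn.Conv2d(c, 1, 1, bias=True, rng=rng)

    # -- inference ---------------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        n, h, w, c = x.shape
        if c != self.config.input_channels:
            raise ValueError(f"expected {self.config.input_channels}-channel "
                             f"input, got {c}")
        if h % 8 or w % 8:
            raise ValueError(
                f"input spatial dims must be divisible by 8, got {h}x{w}")

    def forward(self, x: Tensor, return_logits: bool = False) -> Tensor:
        self._check_input(x)
        x = self.stem(x)
        skips = []
        for blk, tr in zip(self.enc_blocks, self.transitions):
            x = blk(x)
            skips.append(x)
            x = tr(x)
        x = self.center(x)
        for i, blk in enumerate(self.dec_blocks):
            x = self.upsamples[i](x)
            x = nn.concat([skips[-1 - i], x], axis=-1)
            if self.attn_blocks is not None:
                x = self.attn_blocks[i](x)
            x = blk(x)
        logits = self.head(x)
        if return_logits:
            return logits
        return nn.sigmoid(logits)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one slice (H, W) or a batch (N, H, W)."""
        arr = np.asarray(image, dtype=np.float32)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected (H, W) or (N, H, W), got {arr.shape}")
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(Tensor(arr[..., None]))
        finally:
            if was_training:
                self.train()
        probs = out.data[..., 0]
        return probs[0] if squeeze else probs


def build_model(config: ModelConfig | None = None, seed: int = 0
                ) -> SegmentationModel:
    """Instantiate a variant with He-normal weights (seeded)."""
    return SegmentationModel(config or ModelConfig(), seed=seed)


def count_parameters(model: SegmentationModel) -> ParamCount:
    """Walk the layer list and count every stored parameter."""
    trainable = 0
    frozen = 0
    for p in model.parameters():
        if p.trainable:
            trainable += p.size
        else:
            frozen += p.size
    return ParamCount(trainable + frozen, trainable, frozen)


def bn_channel_sum(model: nn.Module) -> int:
    """Sum of batch-norm channel widths across the model."""
    return sum(m.channels for m in model.modules()
               if isinstance(m, nn.BatchNorm2d))


def he_normal_init(fan_in: int, shape,
                   rng: np.random.Generator | int | None = 0) -> np.ndarray:
    """He-normal truncated draws: sigma = sqrt(2/fan_in), cut at +/-2 sigma."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return nn.he_normal(shape, fan_in, rng)


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map to {0,1} with a strict > rule."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (np.asarray(prob_map) > threshold).astype(np.uint8)


# -- checkpoints ------------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path) -> None:
    """Serialise weights + config to a single ``.npz`` archive."""
    import json

    state = model.state_dict()
    meta = dict(config=asdict(model.config), seed=model.seed)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SegmentationModel:
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("dilation_rates", "patch_schedule"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = build_model(ModelConfig(**cfg_dict), seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model
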