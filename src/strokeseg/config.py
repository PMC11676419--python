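"""Run configuration: the training recipe plus model/pipeline knobs.

Defaults reproduce the reference recipe (3x3 kernels, batch 8, ReLU,
dropout 0.2, learning rate 1e-4, Adam, 100 epochs, BCE-Dice loss) and the
calibrated width schedule; everything is overridable from YAML or CLI flags.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path

import yaml

from .model import ModelConfig

__all__ = ["RunConfig", "load_config", "default_config_text"]


@dataclass
class RunConfig:
    # training recipe
    loss: str = "bce_dice"
    batch_size: int = 8
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    epochs: int = 100
    seed: int = 0
    train_fraction: float = 0.8
    split_by_subject: bool = True
    # preprocessing
    target_size: int = 192
    fg_threshold: float = 0.02
    augmentation_factor: int = 3
    # model
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.target_size % 8:
            raise ValueError("target_size must be divisible by 8")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["model"] = asdict(self.model)
        return d


def _coerce_model(d: dict) -> ModelConfig:
    for key in ("dilation_rates", "patch_schedule"):
        if key in d:
            d[key] = tuple(d[key])
    return ModelConfig(**d)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML run config (the packaged default when ``path`` is None)
    and apply keyword overrides.  Model-level overrides are passed under a
    ``model`` dict or as ``model__<field>`` keys."""
    if path is None:
        raw = yaml.safe_load(default_config_text())
    else:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    model_raw = raw.pop("model", {})
    known = {f.name for f in fields(RunConfig)} - {"model"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in overrides.items():
        if key.startswith("model__"):
            model_raw[key[len("model__"):]] = value
        elif value is not None:
            raw[key] = value
    return RunConfig(model=_coerce_model(model_raw), **raw)


def default_config_text() -> str:
    return (resources.files("strokeseg") / "configs" /
            "default.yaml").read_text()
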