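"""YAML configuration for architecture, losses and training.

Layout mirrors the dataclasses::

    model:  {stage_channels: [32,64,128,256,256], kernel_mode: series, ...}
    critic: {block_channels: [64,64,32,32], fc_units: 32}
    loss:   {alpha: 0.1, reduction: mean, adv_weight: 0.01}
    train:  {n_critic: 5, clip_c: 0.01, lr_generator: 5.0e-5, ...}

Any key may be omitted; defaults are the dataclass defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .discriminator import CriticSpec
from .generator import ArchSpec
from .losses import LossConfig
from .training import TrainConfig

__all__ = ["load_config", "config_from_dict"]


def _build(cls, raw: dict | None):
    raw = dict(raw or {})
    allowed = {f.name for f in fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key, value in raw.items():
        if isinstance(value, list):
            raw[key] = tuple(value)
    return cls(**raw)


def config_from_dict(raw: dict) -> TrainConfig:
    raw = dict(raw or {})
    train_kwargs = dict(raw.get("train") or {})
    allowed = {f.name for f in fields(TrainConfig)} - {"arch", "critic", "loss"}
    unknown = set(train_kwargs) - allowed
    if unknown:
        raise ValueError(f"unknown train keys: {sorted(unknown)}")
    return TrainConfig(
        arch=_build(ArchSpec, raw.get("model")),
        critic=_build(CriticSpec, raw.get("critic")),
        loss=_build(LossConfig, raw.get("loss")),
        **train_kwargs,
    )


def load_config(path) -> TrainConfig:
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)
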