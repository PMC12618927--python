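"""YAML-backed configuration for the CLI and training scripts."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .codec import CodecConfig, TrainConfig
from .errors import ConfigurationError
from .vae import LossWeights

__all__ = ["load_config", "dump_config"]


def load_config(path) -> tuple[CodecConfig, TrainConfig]:
    """Read a YAML file with optional ``codec:`` and ``train:`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    codec_kw = dict(raw.get("codec", {}))
    for key in ("image_hw", "channels"):
        if key in codec_kw:
            codec_kw[key] = tuple(codec_kw[key])
    train_kw = dict(raw.get("train", {}))
    if "loss_weights" in train_kw:
        train_kw["loss_weights"] = LossWeights(**train_kw["loss_weights"])
    try:
        return CodecConfig(**codec_kw), TrainConfig(**train_kw)
    except TypeError as exc:
        raise ConfigurationError(f"bad config key: {exc}") from None


def dump_config(codec: CodecConfig, train: TrainConfig, path) -> None:
    payload = {"codec": asdict(codec), "train": asdict(train)}
    payload["codec"]["image_hw"] = list(codec.image_hw)
    payload["codec"]["channels"] = list(codec.channels)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
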