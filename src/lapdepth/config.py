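"""Run configuration: one YAML file with per-stage blocks.

Every field has a default, unknown keys are rejected, and the whole
configuration hashes to a stable hex digest recorded in run manifests so an
experiment is reproducible from its config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .confidence import DistillationParams
from .losses import LossWeights
from .network import ModelConfig, TrainConfig
from .stereo_core import StereoParams


@dataclass
class SynthConfig:
    n_scenes: int = 4
    width: int = 64
    height: int = 64
    d_min: float = 2.0
    d_max: float = 12.0
    smoothness: float = 0.15
    texture_octaves: int = 4
    noise_sigma: float = 0.0


@dataclass
class EvalConfig:
    min_points: int = 10_000
    tau_bg: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    synth: SynthConfig = field(default_factory=SynthConfig)
    stereo: StereoParams = field(default_factory=lambda: StereoParams(1, 14))
    confidence: DistillationParams = field(default_factory=DistillationParams)
    loss: LossWeights = field(default_factory=LossWeights)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


_BLOCKS = {
    "synth": SynthConfig, "stereo": StereoParams,
    "confidence": DistillationParams, "loss": LossWeights,
    "model": ModelConfig, "train": TrainConfig, "eval": EvalConfig,
}


class ConfigError(ValueError):
    """A configuration file did not validate."""


def _build(cls, payload: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``overrides`` maps dotted keys
    (e.g. ``train.lr``) to replacement values."""
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError("top-level config must be a mapping")
    for key, value in (overrides or {}).items():
        block, _, leaf = key.partition(".")
        if leaf:
            payload.setdefault(block, {})[leaf] = value
        else:
            payload[block] = value

    kwargs: dict = {}
    for key, value in payload.items():
        if key in _BLOCKS:
            if not isinstance(value, dict):
                raise ConfigError(f"block {key!r} must be a mapping")
            value = dict(value)
            if key == "train" and "weights" in value:
                value["weights"] = _build(LossWeights, value["weights"],
                                          "train.weights")
            if key == "train" and "lr_schedule" in value:
                value["lr_schedule"] = tuple(
                    (int(e), float(f)) for e, f in value["lr_schedule"])
            if key == "stereo" and "census_window" in value:
                value["census_window"] = tuple(value["census_window"])
            kwargs[key] = _build(_BLOCKS[key], value, f"block {key!r}")
        elif key in ("seed", "out_dir"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    cfg = RunConfig(**kwargs)
    # a single seed steers every stage unless a stage overrides it
    if "train" not in payload or "seed" not in payload.get("train", {}):
        cfg.train.seed = cfg.seed
    return cfg


def config_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the full configuration (any change changes it)."""
    canon = json.dumps(config_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
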