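"""Run configuration: one YAML file reaches every stage parameter.

Unknown keys are rejected so typos fail loudly instead of silently using
defaults. CLI flags override file values.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .changedet import OpeningConfig, RegistrationConfig
from .core import UNIFIED_RESOLUTION_CM
from .evalmetrics import BufferSpec
from .mosaic import InferenceConfig
from .segnet import AugmentConfig, NetworkConfig, TrainConfig
from .synthgen import SceneConfig
from .trailcompass import DirectionConfig


@dataclass
class RunConfig:
    seed: int = 0
    resolution_cm_per_px: float = UNIFIED_RESOLUTION_CM
    log_level: str = "INFO"
    scene: SceneConfig = field(default_factory=SceneConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    opening: OpeningConfig = field(default_factory=OpeningConfig)
    direction: DirectionConfig = field(default_factory=DirectionConfig)
    buffer: BufferSpec = field(default_factory=BufferSpec)


def _build(dc_cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(dc_cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys under '{path}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(dc_cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return dc_cls(**kwargs)


_SUB_CONFIGS = {
    "scene": SceneConfig, "network": NetworkConfig, "train": TrainConfig,
    "augment": AugmentConfig, "inference": InferenceConfig,
    "registration": RegistrationConfig, "opening": OpeningConfig,
    "direction": DirectionConfig, "buffer": BufferSpec,
}


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping")
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SUB_CONFIGS:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build(_SUB_CONFIGS[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_digest(cfg: RunConfig) -> str:
    """Stable short hash of the effective configuration (for run logs)."""
    import hashlib
    import json

    text = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
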