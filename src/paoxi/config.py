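"""Run configuration: YAML schema, defaults, strict loading, seed streams."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .phantom import PhantomConfig

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class LocTrainSection:
    batch_size: int = 4
    learning_rate: float = 1e-4
    epochs: int = 2000
    dropout_p: float = 0.5
    base_features: int = 8
    levels: int = 4
    heatmap_sigma: float = 3.0
    augment_geometric: bool = True
    channel_subset_prob: float = 0.5


@dataclass
class BaselineTrainSection:
    batch_size: int = 8
    learning_rate: float = 1e-6
    epochs: int = 10000


@dataclass
class UnmixSection:
    o2sat_step: float = 1.0
    fit_scale: bool = True
    region_h: int = 50
    region_w: int = 80


@dataclass
class RoiSection:
    a: int = 1
    b: int = -4
    c: int = 4
    d: int = 11
    sigma: float = 1.0


@dataclass
class McdSection:
    mode: str = "combined"
    n_model: int = 20
    n_data: int = 20


@dataclass
class PathsSection:
    data: str = "study.h5"
    models: str = "models"
    outputs: str = "outputs"


@dataclass
class RunConfig:
    seed: int = 0
    paths: PathsSection = field(default_factory=PathsSection)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    train: LocTrainSection = field(default_factory=LocTrainSection)
    baseline_train: BaselineTrainSection = field(default_factory=BaselineTrainSection)
    unmix: UnmixSection = field(default_factory=UnmixSection)
    roi: RoiSection = field(default_factory=RoiSection)
    mcd: McdSection = field(default_factory=McdSection)

    def seed_streams(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def _update_dataclass(obj, data: dict, path: str) -> None:
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ConfigError(f"unknown configuration key {path}{key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and not isinstance(current, type):
            if not isinstance(value, dict):
                raise ConfigError(f"section {path}{key!r} must be a mapping")
            _update_dataclass(current, value, f"{path}{key}.")
        else:
            if value is not None and current is not None:
                want = type(current)
                if want in (int, float) and isinstance(value, bool):
                    raise ConfigError(f"{path}{key}: expected {want.__name__}, got bool")
                if want is float and isinstance(value, int):
                    value = float(value)
                if want is tuple and isinstance(value, list):
                    value = tuple(value)
                if not isinstance(value, want):
                    raise ConfigError(
                        f"{path}{key}: expected {want.__name__}, "
                        f"got {type(value).__name__}"
                    )
            setattr(obj, key, value)


def load_config(path_or_stream) -> RunConfig:
    """Load a YAML run configuration, filling defaults and rejecting unknown keys."""
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            data = yaml.safe_load(fh)
    cfg = RunConfig()
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise ConfigError("top-level configuration must be a mapping")
    _update_dataclass(cfg, data, "")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    import hashlib
    import json

    return hashlib.sha256(
        json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
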