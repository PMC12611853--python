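"""Run configuration: one nested, schema-checked mapping for every stage.

Unknown keys are rejected so that typos in YAML files fail loudly;
``parse(serialize(config)) == config`` round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activations import ActivationSpec
from .models import ModelConfig
from .preprocessing import (DiffusionParams, PreprocessConfig, RegionCriteria,
                            StructuringElement)
from .synthetic import PhantomConfig
from .train_eval import TrainConfig

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    data: PhantomConfig = field(default_factory=PhantomConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)


_NESTED = {
    PreprocessConfig: {"diffusion": DiffusionParams,
                       "opening_selem": StructuringElement,
                       "region_criteria": RegionCriteria,
                       "dilation_selem": StructuringElement},
    RunConfig: {"data": PhantomConfig, "preprocessing": PreprocessConfig,
                "model": ModelConfig, "training": TrainConfig},
    ModelConfig: {"activation": ActivationSpec},
}


def _build(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    sub = _NESTED.get(cls, {})
    for key, value in mapping.items():
        if key in sub and isinstance(value, dict):
            kwargs[key] = _build(sub[key], value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def _dump(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _dump(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def from_dict(mapping: dict) -> RunConfig:
    return _build(RunConfig, mapping or {})


def to_dict(config: RunConfig) -> dict:
    return _dump(config)


def load(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh) or {})


def save(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)
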