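"""Run configuration: one YAML file drives an end-to-end run.

A :class:`RunConfig` nests the per-module configurations (simulation,
cleaning, augmentation, training) plus the model choice and a single seed
from which all randomness flows. Unknown keys are rejected so typos fail
before any stage executes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .preprocess import CleaningConfig
from .sensor_sim import SimConfig
from .training import TrainConfig

MODEL_FAMILIES = ("drosophila_net", "inception_fly", "spectrogram_net")
FEATURE_KINDS = ("waveform", "psd", "spectrogram")


class ConfigError(ValueError):
    pass


def _build(cls, data: dict | None, section: str):
    data = dict(data or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        # YAML lists become the tuples several configs expect
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


@dataclass(frozen=True)
class ModelConfig:
    family: str = "drosophila_net"
    feature: str = "waveform"
    n_blocks: int = 8
    base_filters: int = 16

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}")
        if self.feature not in FEATURE_KINDS:
            raise ValueError(f"feature must be one of {FEATURE_KINDS}")
        if self.family == "spectrogram_net" and self.feature != "spectrogram":
            raise ValueError("spectrogram_net requires the spectrogram feature")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {"seed", "sim", "cleaning", "augment", "model", "train"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        sim = dict(data.get("sim") or {})
        sim.setdefault("rng_seed", data.get("seed", 0))
        train = dict(data.get("train") or {})
        train.setdefault("seed", data.get("seed", 0))
        return cls(seed=int(data.get("seed", 0)),
                   sim=_build(SimConfig, sim, "sim"),
                   cleaning=_build(CleaningConfig, data.get("cleaning"), "cleaning"),
                   augment=_build(AugmentConfig, data.get("augment"), "augment"),
                   model=_build(ModelConfig, data.get("model"), "model"),
                   train=_build(TrainConfig, train, "train"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
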