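"""Pipeline configuration: YAML round-trip, validation, seed fan-out.

One global integer seed is fanned out to per-stage seeds by a documented
hash (crc32 of the stage name mixed into the seed, reduced mod 2^31) so each
stage is independently reproducible without the user bookkeeping seeds.
Unknown configuration keys are hard errors.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .augment import AugmentConfig, SplitRatios
from .preprocess import PreprocessConfig
from .training import TrainConfig

__all__ = ["SynthConfig", "NetworkConfig", "PipelineConfig", "stage_seed",
           "load_config", "save_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: (seed * 2654435761 + crc32(stage)) mod 2^31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass(frozen=True)
class SynthConfig:
    counts_per_class: tuple[int, ...] = (24,) * 8
    class_names: tuple[str, ...] | None = None
    image_size: int = 224
    n_classes: int = 8
    background_level: float = 0.05


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "hp"          # 'baseline' or 'hp'
    preset: str = "full"         # 'full' (stock stage table) or 'small'
    n_classes: int = 8
    input_size: int = 224


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    workdir: str = "runs/pipeline"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    split: SplitRatios = field(default_factory=SplitRatios)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


def _from_dict(cls, data, path="config"):
    if not isinstance(data, dict):
        raise TypeError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise KeyError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[key] = _from_dict(f.type, value, f"{path}.{key}")
        elif isinstance(value, dict):
            # nested dataclass declared via string annotation
            sub = _FIELD_TYPES.get((cls, key))
            if sub is None:
                raise TypeError(f"{path}.{key}: unexpected mapping")
            kwargs[key] = _from_dict(sub, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_FIELD_TYPES = {
    (PipelineConfig, "synth"): SynthConfig,
    (PipelineConfig, "preprocess"): PreprocessConfig,
    (PipelineConfig, "augment"): AugmentConfig,
    (PipelineConfig, "split"): SplitRatios,
    (PipelineConfig, "network"): NetworkConfig,
    (PipelineConfig, "train"): TrainConfig,
}


def _to_plain(obj):
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)
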