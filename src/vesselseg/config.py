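"""YAML-backed run configuration with strict key validation.

Every field has a default, unknown keys are rejected by name, and one
global seed deterministically derives the per-stage seeds so a run is
reproducible from its effective-config echo alone.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .model import NetworkSpec
from .preprocess import PreprocessConfig
from .synthetic import SynthConfig
from .train import TrainConfig

__all__ = [
    "ConfigError",
    "SamplerSection",
    "InferSection",
    "PipelineSection",
    "RunConfig",
    "parse_config",
    "derive_stage_seed",
    "effective_config_yaml",
]


class ConfigError(ValueError):
    pass


@dataclass
class SamplerSection:
    n_total: int = 190_000
    patch_size: int = 48
    val_fraction: float = 0.1


@dataclass
class InferSection:
    stride: int = 8
    threshold: float = 0.5
    batch_size: int = 64


@dataclass
class PipelineSection:
    data_dir: str | None = None
    n_train: int = 10
    n_test: int = 5


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sampler: SamplerSection = field(default_factory=SamplerSection)
    model: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    infer: InferSection = field(default_factory=InferSection)
    synth: SynthConfig = field(default_factory=SynthConfig)
    pipeline: PipelineSection = field(default_factory=PipelineSection)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "sampler": SamplerSection,
    "model": NetworkSpec,
    "train": TrainConfig,
    "infer": InferSection,
    "synth": SynthConfig,
    "pipeline": PipelineSection,
}
_SCALARS = {"seed": int, "log_level": str}


def _coerce(section: str, name: str, value, declared_type: str):
    """Loose-but-safe coercion from YAML scalars to field types."""
    if value is None and "None" in declared_type:
        return None
    if "tuple" in declared_type:
        if not isinstance(value, (list, tuple)):
            raise ConfigError(f"{section}.{name}: expected a list, got {value!r}")
        return tuple(value)
    if declared_type.startswith("int"):
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{section}.{name}: expected an integer, got {value!r}")
        return value
    if declared_type.startswith("float"):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{section}.{name}: expected a number, got {value!r}")
        return float(value)
    if declared_type.startswith("str"):
        if not isinstance(value, str):
            raise ConfigError(f"{section}.{name}: expected a string, got {value!r}")
        return value
    return value


def _build_section(section_name: str, cls, values: dict):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, val in values.items():
        if key not in known:
            raise ConfigError(f"unknown config key: {section_name}.{key}")
        kwargs[key] = _coerce(section_name, key, val, str(known[key].type))
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section_name} config: {exc}") from exc


def parse_config(
    path: str | Path | None = None, overrides: list[str] | None = None
) -> RunConfig:
    """Build a fully-defaulted RunConfig from a YAML file plus overrides.

    Overrides are ``section.key=value`` strings whose values are parsed
    as YAML scalars. Unknown keys raise :class:`ConfigError` naming the
    offending key.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigError(f"override must look like section.key=value, got {ov!r}")
        dotted, _, raw_val = ov.partition("=")
        value = yaml.safe_load(raw_val)
        parts = dotted.strip().split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    kwargs = {}
    for key, val in data.items():
        if key in _SCALARS:
            kwargs[key] = _coerce("<root>", key, val, _SCALARS[key].__name__)
        elif key in _SECTIONS:
            if not isinstance(val, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(key, _SECTIONS[key], val)
        else:
            raise ConfigError(f"unknown config key: {key}")
    return RunConfig(**kwargs)


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the global seed."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0])


def effective_config_yaml(cfg: RunConfig) -> str:
    """Serialize the fully-defaulted config (the reproducibility echo)."""

    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    return yaml.safe_dump(clean(cfg), sort_keys=True)
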