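"""Run configuration: nested architecture/training constants plus paths.

Config files are YAML (or JSON, a YAML subset) mirroring
:class:`~ddisiam.model.ModelConfig` and
:class:`~ddisiam.training.TrainConfig` field-for-field under ``model:``
and ``training:`` keys; unknown keys are rejected so typos fail loudly.
Dotted-key overrides (``training.epochs=20``) are supported for
command-line tweaking.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig


class ConfigError(ValueError):
    """Raised on schema violations; message lists every violation."""


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    descriptor_file: str | None = None
    pair_file: str | None = None
    output_dir: str = "."
    verbosity: str = "info"

    def validate_paths(self) -> None:
        problems = []
        for name in ("descriptor_file", "pair_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name}: path does not exist: {p}")
        if problems:
            raise ConfigError("; ".join(problems))


def _build(cls, data: dict, prefix: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    errors = [f"{prefix}: unknown key {k!r}" for k in unknown]
    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{prefix}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    top = {"model", "training", "descriptor_file", "pair_file", "output_dir", "verbosity"}
    unknown = sorted(set(data) - top)
    if unknown:
        raise ConfigError("; ".join(f"unknown top-level key {k!r}" for k in unknown))
    model = _build(ModelConfig, dict(data.pop("model", {}) or {}), "model")
    training = _build(TrainConfig, dict(data.pop("training", {}) or {}), "training")
    return RunConfig(model=model, training=training, **data)


def load_config(path: str | Path, overrides: dict[str, object] | None = None) -> RunConfig:
    """Load a YAML/JSON run config, applying dotted-key overrides."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override {key!r} descends through a non-mapping")
        node[parts[-1]] = value
    return config_from_dict(data)


def parse_override(text: str) -> tuple[str, object]:
    """Parse a ``dotted.key=value`` override; values are YAML-typed."""
    if "=" not in text:
        raise ConfigError(f"override must look like key=value, got {text!r}")
    key, raw = text.split("=", 1)
    return key.strip(), yaml.safe_load(raw)
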