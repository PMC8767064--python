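"""Pipeline configuration: YAML in, validated dataclasses out."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .effects import ClassifierThresholds
from .preprocess import PreprocessParams
from .synthetic import GeneratorConfig


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    thresholds: ClassifierThresholds = field(
        default_factory=ClassifierThresholds
    )
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    #: number of PC-space components used for part distances
    trajectory_k: int = 3
    cluster_k: int = 6
    cluster_n_init: int = 10
    cluster_delta: float = 0.5
    cluster_metric: str = "euclidean"
    #: compartments whose profiles feed the coexpression clustering
    cluster_tissues: tuple[str, ...] = ("EnU", "EnB")
    enrich_alpha: float = 0.05


_SECTION_TYPES = {
    "generator": GeneratorConfig,
    "thresholds": ClassifierThresholds,
    "preprocess": PreprocessParams,
}

_SCALARS = {
    "trajectory_k": int,
    "cluster_k": int,
    "cluster_n_init": int,
    "cluster_delta": float,
    "cluster_metric": str,
    "cluster_tissues": tuple,
    "enrich_alpha": float,
}


def _coerce(value, target_type):
    if target_type is tuple and isinstance(value, list):
        return tuple(value)
    return value


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; absent keys keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    for key, val in doc.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name: f.type for f in dataclasses.fields(cls)}
            unknown = set(val) - set(valid)
            if unknown:
                raise ValueError(
                    f"{path}: unknown {key} option(s): {sorted(unknown)}"
                )
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in val.items()
            }
            setattr(cfg, key, cls(**kwargs))
        elif key in _SCALARS:
            setattr(cfg, key, _coerce(val, _SCALARS[key]))
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    cfg.generator.validate()
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the fully resolved configuration."""
    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {
                f.name: encode(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, (tuple, list)):
            return [encode(x) for x in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in sorted(obj.items())}
        return obj

    blob = json.dumps(encode(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
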