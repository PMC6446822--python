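"""Configuration files, validation and run manifests.

Experiment configurations are flat YAML documents whose keys match
:class:`~ridlsim.experiments.ExperimentConfig` field names, with nested
``strategy``, ``regime``, ``selection`` and ``demography`` sections for
the corresponding parameter groups, plus a top-level ``experiment`` key
(1 or 2) selecting the design.  Every run writes a JSON manifest holding
the fully resolved configuration, the master seed and the derived
per-replicate seeds; re-running from a manifest's snapshot reproduces
the trajectory byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .experiments import ExperimentConfig
from .genetics import SelectionParams
from .lifecycle import DemographyParams
from .metapop import ReleaseStrategy, SelectionRegime

__all__ = [
    "ConfigError",
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "RunManifest",
    "write_manifest",
    "read_manifest",
]


class ConfigError(ValueError):
    """A malformed configuration; the message names the offending field."""


_SECTIONS = {
    "strategy": ReleaseStrategy,
    "regime": SelectionRegime,
    "selection": SelectionParams,
    "demography": DemographyParams,
}

_TUPLE_FIELDS = {"toxin_survival_by_r", "heterogeneous_refuges"}


def _build_section(name: str, cls, data: Any):
    if not isinstance(data, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"{name}.{key}: unknown field")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def config_from_dict(data: dict) -> tuple[int, ExperimentConfig]:
    """Build (experiment number, config) from a parsed document."""
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    data = dict(data)
    experiment = data.pop("experiment", 1)
    if experiment not in (1, 2):
        raise ConfigError(f"experiment: must be 1 or 2, got {experiment!r}")
    top_fields = {f.name for f in dataclasses.fields(ExperimentConfig)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _build_section(key, _SECTIONS[key], value)
        elif key in top_fields:
            kwargs[key] = value
        else:
            raise ConfigError(f"{key}: unknown field")
    try:
        config = ExperimentConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return int(experiment), config


def load_config(path: str | Path) -> tuple[int, ExperimentConfig]:
    """Parse a YAML configuration file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return config_from_dict(data or {})


def config_to_dict(experiment: int, config: ExperimentConfig) -> dict:
    """Fully resolved, JSON/YAML-serializable configuration snapshot."""
    out: dict[str, Any] = {"experiment": experiment}
    for f in dataclasses.fields(ExperimentConfig):
        value = getattr(config, f.name)
        if f.name in _SECTIONS:
            out[f.name] = {
                sf.name: (
                    list(v)
                    if isinstance(v := getattr(value, sf.name), tuple)
                    else v
                )
                for sf in dataclasses.fields(type(value))
            }
        else:
            out[f.name] = value
    return out


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written alongside every trajectory."""

    config: dict
    master_seed: int
    replicate_seeds: list[list[int]]
    version: str
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def derive_replicate_seeds(master_seed: int, n_streams: int) -> list[list[int]]:
    """Spawn keys of the per-replicate seed sequences, for the manifest."""
    ss = np.random.SeedSequence(master_seed)
    return [list(child.spawn_key) for child in ss.spawn(n_streams)]


def write_manifest(
    path: str | Path,
    experiment: int,
    config: ExperimentConfig,
    n_streams: int,
    outputs: list[str],
    version: str,
) -> RunManifest:
    manifest = RunManifest(
        config=config_to_dict(experiment, config),
        master_seed=config.master_seed,
        replicate_seeds=derive_replicate_seeds(config.master_seed, n_streams),
        version=version,
        outputs=[str(o) for o in outputs],
    )
    Path(path).write_text(manifest.to_json() + "\n")
    return manifest


def read_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
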