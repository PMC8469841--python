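"""Run configuration: YAML parsing, validation, defaults, and manifests.

A :class:`RunConfig` composes the observation geometry, training
hyperparameters, localization protocol and phantom generator settings.
Every field has a default (matching the full-scale protocol where one is
stated: N=32, H=3, gamma=0.9, batch 48, replay 1.5e5, 1500-step episodes,
rho=3, epsilon 0.9 -> 0.1), so an empty config file is a valid complete
configuration.  Unknown keys are rejected with the offending name.

All randomness in a run flows from one root seed, split into named
substreams (network init, environment, replay sampling, agent spawning) via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .localization import LocalizationConfig
from .phantom import PhantomConfig
from .training import TrainConfig
from .volume_env import ObservationSpec

__all__ = ["RunConfig", "parse_config", "dump_config", "config_to_dict", "run_manifest"]


@dataclass(frozen=True)
class RunConfig:
    observation: ObservationSpec = field(default_factory=ObservationSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)


_SECTIONS = {
    "observation": ObservationSpec,
    "train": TrainConfig,
    "localization": LocalizationConfig,
    "phantom": PhantomConfig,
}

# fields whose YAML lists must become tuples
_TUPLE_FIELDS = {
    "window",
    "dims",
    "spacing_mm",
    "sphere_radius_range",
    "encoder_channels",
    "fine_start_radius",
}


def _build_section(cls, data: dict[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"valid keys: {sorted(names)}"
        )
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {section!r}: {exc}") from exc


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; an empty/missing file gives defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        data = loaded
    if overrides:
        for section, vals in overrides.items():
            data.setdefault(section, {}).update(vals)
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(
            f"unknown config section(s) {sorted(unknown)}; valid: {sorted(_SECTIONS)}"
        )
    sections = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**sections)


def config_to_dict(cfg: RunConfig) -> dict:
    """Fully resolved configuration (defaults filled in) as plain data."""
    out: dict[str, Any] = {}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(cfg, name))
        out[name] = {
            k: list(v) if isinstance(v, tuple) else v for k, v in section.items()
        }
    return out


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def run_manifest(cfg: RunConfig, extra: dict | None = None) -> dict:
    """Everything needed to reproduce a run: resolved config, seeds, version."""
    from . import __version__

    manifest = {
        "version": __version__,
        "config": config_to_dict(cfg),
        "seeds": {
            "train": cfg.train.seed,
            "localization": cfg.localization.seed,
            "phantom": cfg.phantom.seed,
        },
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))
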