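"""Run configuration: defaults, YAML/JSON loading, validation, round-trip.

A run configuration is a nested structure of plain dataclasses.  ``load_config``
reads YAML (JSON is a YAML subset), overlays the file's values onto the
defaults, rejects unknown keys by full path, and validates cross-field
constraints.  ``serialize_config`` inverts the mapping so that
``load`` (serialize(cfg)) == cfg.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .affect import HRCParams, PainParams
from .environment import (
    SPECIES,
    SpeciesParams,
    WorldConfig,
    default_species_params,
    validate_species_set,
)
from .errors import ConfigurationError
from .forager import ForagerParams, SensorParams
from .learning import LearningParams

RE_BAND = (-20.0, 20.0)  # admissible reward-experience clamp range
S_BAND = (0.01, 1.0)     # admissible satiation clamp range


def _default_satiation_axis() -> list[float]:
    return [0.01] + [round(0.1 * k, 1) for k in range(1, 11)]


def _default_re_axis() -> list[float]:
    return [float(v) for v in range(-20, 25, 5)]


def _default_pain_re_axis() -> list[float]:
    return [float(v) for v in range(-10, 12, 2)]


def _default_phase_ticks() -> dict[str, int]:
    return {
        "prey_only": 5000,
        "drug_introduced": 10000,
        "drug_removed": 5000,
        "drug_without_reward": 10000,
    }


@dataclass
class ExperimentConfig:
    """Protocol schedule, sweep axes, and presentation geometry."""

    trials: int = 10
    seed: int = 0
    satiation_axis: list[float] = field(default_factory=_default_satiation_axis)
    re_axis: list[float] = field(default_factory=_default_re_axis)
    pain_re_axis: list[float] = field(default_factory=_default_pain_re_axis)
    t_present: int = 300        # ticks per presentation trial
    t_equilibrate: int = 200    # field pre-equilibration ticks
    item_bearing: float = 45.0  # degrees left of heading
    item_distance: float = 5.0  # patches
    presentation_arena: int = 40
    dead_zone: float = 5.0      # degrees; |net turn| below this is 'none'
    pain_strength: float = 10.0
    pain_bearing: float = -45.0  # right anterior
    phase_ticks: dict[str, int] = field(default_factory=_default_phase_ticks)
    n_hermi: int = 3
    n_flab: int = 3
    n_drug: int = 6
    satiation_fixation: float | None = None
    reward_experience_fixation: float | None = None

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ConfigurationError(f"experiment.trials must be >= 1, got {self.trials}")
        if self.dead_zone <= 0:
            raise ConfigurationError(
                f"experiment.dead_zone must be > 0, got {self.dead_zone}"
            )
        if self.pain_strength < 0:
            raise ConfigurationError(
                f"experiment.pain_strength must be >= 0, got {self.pain_strength}"
            )
        for axis_name in ("satiation_axis", "re_axis", "pain_re_axis"):
            axis = getattr(self, axis_name)
            if any(b <= a for a, b in zip(axis, axis[1:])):
                raise ConfigurationError(
                    f"experiment.{axis_name} must be strictly increasing"
                )
        for key in self.phase_ticks:
            if key not in _default_phase_ticks():
                raise ConfigurationError(
                    f"experiment.phase_ticks.{key} is not a known phase"
                )
        if self.satiation_fixation is not None and not (
            S_BAND[0] <= self.satiation_fixation <= S_BAND[1]
        ):
            raise ConfigurationError(
                f"experiment.satiation_fixation must be in [{S_BAND[0]}, {S_BAND[1]}], "
                f"got {self.satiation_fixation}"
            )
        if self.reward_experience_fixation is not None and not (
            RE_BAND[0] <= self.reward_experience_fixation <= RE_BAND[1]
        ):
            raise ConfigurationError(
                "experiment.reward_experience_fixation must be in "
                f"[{RE_BAND[0]}, {RE_BAND[1]}], got {self.reward_experience_fixation}"
            )


@dataclass
class RunConfig:
    """Complete, serializable description of a run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    species: dict[str, SpeciesParams] = field(default_factory=default_species_params)
    sensors: SensorParams = field(default_factory=SensorParams)
    forager: ForagerParams = field(default_factory=ForagerParams)
    hrc: HRCParams = field(default_factory=HRCParams)
    pain: PainParams = field(default_factory=PainParams)
    learning: LearningParams = field(default_factory=LearningParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    output_dir: str = "results"
    allow_nonstandard_species: bool = False

    def __post_init__(self) -> None:
        missing = [s for s in SPECIES if s not in self.species]
        if missing:
            raise ConfigurationError(f"species block is missing {missing}")
        validate_species_set(self.species, self.allow_nonstandard_species)


def _overlay_dataclass(instance, data: dict, path: str):
    """Overlay a mapping onto a dataclass, rejecting unknown keys by path."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in dataclasses.fields(instance)}
    updates = {}
    for key, value in data.items():
        full = f"{path}.{key}" if path else key
        if key not in known:
            raise ConfigurationError(f"unknown configuration key: {full}")
        current = getattr(instance, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            updates[key] = _overlay_dataclass(current, value, full)
        elif key == "species" and isinstance(value, dict):
            updates[key] = _overlay_species(current, value, full)
        elif key == "phase_ticks" and isinstance(value, dict):
            merged = dict(current)
            merged.update({k: int(v) for k, v in value.items()})
            updates[key] = merged
        else:
            updates[key] = value
    try:
        return dataclasses.replace(instance, **updates)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path or 'config'}: {exc}") from exc


def _overlay_species(
    current: dict[str, SpeciesParams], data: dict, path: str
) -> dict[str, SpeciesParams]:
    out = {k: dataclasses.replace(v) for k, v in current.items()}
    for name, block in data.items():
        full = f"{path}.{name}"
        if name not in out:
            raise ConfigurationError(f"unknown species in config: {full}")
        out[name] = _overlay_dataclass(out[name], block, full)
    return out


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a validated RunConfig from a (possibly empty) mapping."""
    base = RunConfig()
    if not data:
        return base
    cfg = _overlay_dataclass(base, data, "")
    # dataclasses.replace re-runs __post_init__ validation at each level;
    # cross-block species constraints are revalidated here for clarity.
    validate_species_set(cfg.species, cfg.allow_nonstandard_species)
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)


def _to_plain(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {f.name: _to_plain(getattr(value, f.name)) for f in dataclasses.fields(value)}
    if isinstance(value, dict):
        return {k: _to_plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_to_plain(v) for v in value]
    return value


def serialize_config(config: RunConfig) -> dict:
    """Plain-dict form of a config; load_config round-trips it."""
    return _to_plain(config)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(serialize_config(config), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable hex digest of the serialized configuration."""
    import hashlib

    payload = json.dumps(serialize_config(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
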