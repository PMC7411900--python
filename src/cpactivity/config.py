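"""Declarative run configuration with documented defaults.

Plain-text YAML with a versioned schema; unknown keys are errors rather than
being ignored, so a typo cannot silently change an experiment.  Every stage's
parameters are resolvable from defaults, and a config round-trips through
serialization unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohort import (DEFAULT_BOUT_RANGES, DEFAULT_DOMAIN_SHIFT,
                     DEFAULT_LEVEL_PARAMS, GMFCS_LEVELS)
from .features import PLACEMENT_SETS

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class CohortSpec:
    n_per_level: dict[str, int] = field(
        default_factory=lambda: {"I": 10, "II": 20, "III": 8})
    heterogeneity: float = 1.0
    domain_shift: float = DEFAULT_DOMAIN_SHIFT
    protocol_assignment: str = "protocol1"   # or "protocol2" / "alternate"
    level_params: dict[str, dict[str, list[float]]] = field(
        default_factory=lambda: {
            lvl: {k: list(v) for k, v in params.items()}
            for lvl, params in DEFAULT_LEVEL_PARAMS.items()})


@dataclass
class ProtocolSpec:
    trial_duration_s: float = 360.0
    free_living_duration_s: float = 360.0
    bout_ranges: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_BOUT_RANGES.items()})


@dataclass
class FeatureSpec:
    window_s: float = 10.0
    transition_policy: str = "drop"     # or "majority"


@dataclass
class SelectionSpec:
    candidate_k: list[int] = field(default_factory=lambda: [10, 15, 20])
    n_bins: int = 10
    variant: str = "MID"


@dataclass
class ModelSpec:
    n_trees: int = 500
    features_per_node: int | None = None    # None -> tune over mtry_grid
    mtry_grid: list[int] = field(default_factory=lambda: [3, 7, 11])


@dataclass
class EvaluationSpec:
    modes: list[str] = field(default_factory=lambda: ["cv", "freeliving"])
    model_types: list[str] = field(default_factory=lambda: ["G", "GP", "FP"])
    placement_sets: list[str] = field(
        default_factory=lambda: list(PLACEMENT_SETS))
    kfold_k: int = 10


@dataclass
class OutputSpec:
    write_raw: bool = False
    log_level: str = "INFO"


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    master_seed: int = 1
    cohort: CohortSpec = field(default_factory=CohortSpec)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    evaluation: EvaluationSpec = field(default_factory=EvaluationSpec)
    output: OutputSpec = field(default_factory=OutputSpec)


_SECTION_TYPES = {
    "cohort": CohortSpec, "protocol": ProtocolSpec, "features": FeatureSpec,
    "selection": SelectionSpec, "model": ModelSpec,
    "evaluation": EvaluationSpec, "output": OutputSpec,
}


def _build_section(cls, data: Mapping[str, Any], path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown config keys under {path!r}: "
                          f"{sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    data = dict(data)
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    version = data.pop("schema_version", SCHEMA_VERSION)
    if int(version) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    kwargs: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    if "master_seed" in data:
        kwargs["master_seed"] = int(data.pop("master_seed"))
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, Mapping):
                raise ConfigError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    return RunConfig(**kwargs)


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


@dataclass
class Finding:
    level: str      # "error" | "warning"
    message: str


def validate_config(config: RunConfig) -> list[Finding]:
    """Blocking errors and non-blocking warnings; findings are data."""
    findings: list[Finding] = []

    def err(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warn(msg: str) -> None:
        findings.append(Finding("warning", msg))

    for lvl in GMFCS_LEVELS:
        n = config.cohort.n_per_level.get(lvl, 0)
        if n < 1:
            err(f"cohort.n_per_level[{lvl}] must be >= 1")
        elif n < 2 and "GP" in config.evaluation.model_types:
            warn(f"n_per_level[{lvl}] < 2 makes GP LOSO degenerate for that "
                 "level")
    if config.features.window_s <= 0:
        err("features.window_s must be positive")
    if config.features.transition_policy not in ("majority", "drop"):
        err("features.transition_policy must be 'majority' or 'drop'")
    if config.protocol.trial_duration_s < config.features.window_s:
        err("protocol.trial_duration_s shorter than one window")
    if not 0.0 <= config.cohort.domain_shift <= 1.0:
        err("cohort.domain_shift must lie in [0, 1]")
    if config.cohort.protocol_assignment not in ("protocol1", "protocol2",
                                                 "alternate"):
        err("cohort.protocol_assignment must be 'protocol1', 'protocol2' or "
            "'alternate'")
    if config.model.n_trees < 1:
        err("model.n_trees must be >= 1")
    if any(k < 1 for k in config.selection.candidate_k):
        err("selection.candidate_k entries must be >= 1")
    if config.selection.variant != "MID":
        err("only the MID mRMR variant is implemented")
    for ps in config.evaluation.placement_sets:
        if ps not in PLACEMENT_SETS:
            err(f"unknown placement set {ps!r}")
    for mt in config.evaluation.model_types:
        if mt not in ("G", "GP", "FP"):
            err(f"unknown model type {mt!r}")
    for mode in config.evaluation.modes:
        if mode not in ("cv", "freeliving"):
            err(f"unknown evaluation mode {mode!r}")
    if config.evaluation.kfold_k < 2:
        err("evaluation.kfold_k must be >= 2")
    return findings
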