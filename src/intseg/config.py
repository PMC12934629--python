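"""Run configuration: YAML parsing, strict key validation, defaults."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .effects import FDR_FAMILIES
from .simulate import SimulationConfig


class ConfigError(ValueError):
    """Raised for unreadable, ill-typed, or unknown configuration keys."""


@dataclass(frozen=True)
class MetricParams:
    window_width: int = 5
    n_null: int = 100
    fdr_family: str = "metric_level"
    fc_convention: str = "block"

    def __post_init__(self) -> None:
        if self.window_width < 2:
            raise ConfigError("metrics.window_width must be >= 2")
        if self.n_null < 1:
            raise ConfigError("metrics.n_null must be >= 1")
        if self.fdr_family not in FDR_FAMILIES:
            raise ConfigError(f"metrics.fdr_family must be one of {FDR_FAMILIES}")
        if self.fc_convention not in ("block", "pooled"):
            raise ConfigError("metrics.fc_convention must be 'block' or 'pooled'")


@dataclass(frozen=True)
class ExternalData:
    manifest: Path
    partition: Path


@dataclass(frozen=True)
class RunConfig:
    seed: int
    out_dir: Path
    simulation: SimulationConfig | None = None
    external: ExternalData | None = None
    metrics: MetricParams = field(default_factory=MetricParams)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.external is None):
            raise ConfigError("exactly one of 'simulation' or 'external' is required")


_SIM_KEYS = {
    "n_rois",
    "network_sizes",
    "n_frames",
    "n_subjects_per_state",
    "w_base",
    "b_base",
    "subject_sd",
    "frame_interval",
}
_METRIC_KEYS = {"window_width", "n_null", "fdr_family", "fc_convention"}
_TOP_KEYS = {"seed", "out_dir", "simulation", "external", "metrics"}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) under {where}: {unknown}")


def validate_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load, default, and strictly validate a YAML run configuration.

    ``seed`` overrides the file's seed (the CLI --seed flag).  A seed is
    mandatory whenever a stochastic stage (simulation or efficiency nulls)
    will run, i.e. always.
    """
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    _check_keys(raw, _TOP_KEYS, "<top level>")

    if seed is None:
        seed = raw.get("seed")
    if seed is None:
        raise ConfigError("a seed is required (config key 'seed' or --seed)")
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError("seed must be an integer")

    if "out_dir" not in raw:
        raise ConfigError("missing required key 'out_dir'")
    out_dir = Path(raw["out_dir"])

    simulation = None
    external = None
    if "external" in raw:
        ext = raw["external"] or {}
        _check_keys(ext, {"manifest", "partition"}, "external")
        for key in ("manifest", "partition"):
            if key not in ext:
                raise ConfigError(f"external.{key} is required")
            if not Path(ext[key]).is_file():
                raise ConfigError(f"external.{key} file not found: {ext[key]}")
        external = ExternalData(Path(ext["manifest"]), Path(ext["partition"]))
    else:
        sim = raw.get("simulation") or {}
        _check_keys(sim, _SIM_KEYS, "simulation")
        if "network_sizes" in sim and sim["network_sizes"] is not None:
            sim["network_sizes"] = tuple(sim["network_sizes"])
        try:
            simulation = SimulationConfig(seed=seed, **sim)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulation block: {exc}") from exc

    met = raw.get("metrics") or {}
    _check_keys(met, _METRIC_KEYS, "metrics")
    try:
        metrics = MetricParams(**met)
    except TypeError as exc:
        raise ConfigError(f"invalid metrics block: {exc}") from exc

    return RunConfig(seed=seed, out_dir=out_dir, simulation=simulation,
                     external=external, metrics=metrics)
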