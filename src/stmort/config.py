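"""Run configuration: defaults, validation, round-trip serialization.

The config file is nested YAML with a fixed section layout (scenario, mcmc,
smoothing, gpr, spline, io, plus top-level seed / horizon_year /
standard_year).  Unknown keys and type mismatches are configuration errors
naming the dotted key; an empty file yields all defaults; load -> save ->
load is the identity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid run configuration; message names the offending key."""


@dataclass
class ScenarioConfig:
    n_provinces: int = 31
    first_year: int = 2001
    last_year: int = 2015
    garbage_fraction: float = 0.132
    duplicate_fraction: float = 0.02
    spatial_sd: float = 0.3


@dataclass
class MCMCConfig:
    iterations: int = 10_000
    burnin: int = 5_000
    thin: int = 5


@dataclass
class SmoothConfig:
    lambda_time: float = 2.0
    omega_age: float = 1.0
    zeta_space: float = 0.9
    max_graph_distance: int = 2


@dataclass
class GPConfig:
    kernel: str = "matern52"
    length_scale: float = 10.0
    amplitude_rule: str = "mad"
    amplitude: float = 0.1
    n_draws: int = 1000
    jitter: float = 1.0e-6


@dataclass
class SplineConfig:
    min_points: int = 4


@dataclass
class IOConfig:
    write_draws: bool = False


@dataclass
class RunConfig:
    seed: int = 0
    horizon_year: int = 2030
    standard_year: int = 2015
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    smoothing: SmoothConfig = field(default_factory=SmoothConfig)
    gpr: GPConfig = field(default_factory=GPConfig)
    spline: SplineConfig = field(default_factory=SplineConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {f.name: f.type for f in fields(RunConfig)}


def _apply(obj, data: dict, prefix: str) -> None:
    valid = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        dotted = f"{prefix}{key}"
        if key not in valid:
            raise ConfigError(f"unknown config key {dotted}")
        current = getattr(obj, key)
        if hasattr(current, "__dataclass_fields__"):
            if not isinstance(value, dict):
                raise ConfigError(f"section {dotted} must be a mapping")
            _apply(current, value, dotted + ".")
            continue
        want = type(current)
        if want is bool:
            if not isinstance(value, bool):
                raise ConfigError(f"type error for {dotted}: expected bool, "
                                  f"got {value!r}")
        elif want is int:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"type error for {dotted}: expected int, "
                                  f"got {value!r}")
        elif want is float:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"type error for {dotted}: expected number, "
                                  f"got {value!r}")
            value = float(value)
        elif want is str:
            if not isinstance(value, str):
                raise ConfigError(f"type error for {dotted}: expected string, "
                                  f"got {value!r}")
        setattr(obj, key, value)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse, validate and default-fill a YAML config file."""
    cfg = RunConfig()
    if path is None:
        return cfg
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _apply(cfg, data, "")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True), encoding="utf-8")
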