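"""Configuration files, CSV readers/writers and run manifests.

Process configurations are human-editable YAML with three layers:
package defaults (the shipped kinetic constants) < scenario file < caller
overrides.  Unknown keys are rejected with the offending key named.
Observation and trajectory CSVs use fixed column schemas with a decimal
point and UTF-8.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ExponentialFeedSpec, GrowthParameters, GrowthState, ProductionParameters
from .simulate import TRAJECTORY_COLUMNS, OilFeedEvent, ProcessConfig, Trajectory
from .synthetic import OBSERVATION_COLUMNS

__all__ = ["load_config", "dump_config", "read_observations",
           "write_observations", "write_trajectory", "read_trajectory",
           "write_report", "RunManifest"]

_REQUIRED_OBS_COLUMNS = ["t_h"]
_CONC_COLUMNS = ["c_x", "c_gluc", "c_nano3", "c_oil", "c_fa", "c_mel", "od625"]


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


def _build(cls, data: dict, context: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"expected a subset of {sorted(known)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


_TOP_KEYS = {
    "name", "initial", "growth_parameters", "production_parameters",
    "feed", "oil_feeds", "t_growth_end", "t_end", "dt_growth",
    "dt_production", "seed", "scale_by_total_biomass",
    "inclusion_by_free_biomass",
}


def load_config(path, overrides: dict | None = None) -> ProcessConfig:
    """Load and validate a process configuration from a YAML file.

    Defaults (shipped kinetic constants, step sizes 0.05/0.2 h) are filled
    for anything the file omits; ``overrides`` is a final mapping layered
    on top of the file's top-level scalar keys.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    raw = {**raw, **(overrides or {})}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    if "initial" not in raw:
        raise ConfigError(f"{path}: missing required 'initial' state")
    for key in ("t_growth_end", "t_end"):
        if key not in raw:
            raise ConfigError(f"{path}: missing required phase timing {key!r}")

    initial = _build(GrowthState, dict(raw["initial"]), "initial state")
    growth = _build(GrowthParameters, dict(raw.get("growth_parameters", {})),
                    "growth_parameters")
    production = _build(ProductionParameters,
                        dict(raw.get("production_parameters", {})),
                        "production_parameters")
    feed = None
    if raw.get("feed") is not None:
        feed = _build(ExponentialFeedSpec, dict(raw["feed"]), "feed")
    oil_feeds = tuple(
        _build(OilFeedEvent, dict(ev), f"oil_feeds[{i}]")
        for i, ev in enumerate(raw.get("oil_feeds", []))
    )
    kwargs = {k: raw[k] for k in
              ("dt_growth", "dt_production", "seed", "scale_by_total_biomass",
               "inclusion_by_free_biomass", "name")
              if k in raw}
    return _build(ProcessConfig, dict(
        initial=initial, growth=growth, production=production, feed=feed,
        oil_feeds=oil_feeds, t_growth_end=float(raw["t_growth_end"]),
        t_end=float(raw["t_end"]), **kwargs), "process config")


def dump_config(config: ProcessConfig, path) -> None:
    """Write a process configuration as YAML (round-trips with load_config)."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    doc = {
        "name": config.name,
        "initial": clean(config.initial),
        "growth_parameters": clean(config.growth),
        "production_parameters": clean(config.production),
        "feed": clean(config.feed) if config.feed is not None else None,
        "oil_feeds": clean(config.oil_feeds),
        "t_growth_end": config.t_growth_end,
        "t_end": config.t_end,
        "dt_growth": config.dt_growth,
        "dt_production": config.dt_production,
        "seed": config.seed,
        "scale_by_total_biomass": config.scale_by_total_biomass,
        "inclusion_by_free_biomass": config.inclusion_by_free_biomass,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV, validating schema and value ranges."""
    table = pd.read_csv(path)
    missing = [c for c in _REQUIRED_OBS_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in table.columns if c not in OBSERVATION_COLUMNS]
    if unknown:
        raise ConfigError(f"{path}: unknown column(s) {unknown}")
    for col in _CONC_COLUMNS:
        if col in table.columns:
            bad = table.index[table[col] < 0]
            if len(bad):
                raise ConfigError(
                    f"{path}: negative {col} at row(s) {list(bad + 2)} "
                    "(1-based, counting the header)")
    if not table["t_h"].is_monotonic_increasing:
        raise ConfigError(f"{path}: t_h must be increasing")
    return table


def write_observations(table: pd.DataFrame, path) -> None:
    cols = [c for c in OBSERVATION_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.12g")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory CSV in the documented fixed column order."""
    traj.frame[TRAJECTORY_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"{path}: missing trajectory column(s) {missing}")
    return frame


def write_report(report: dict, path) -> None:
    """Write a rates/yields/fit report as machine-readable JSON."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(clean(report), indent=2), encoding="utf-8")


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    command: str
    config_hash: str
    parameters: dict
    seed: int | None
    outputs: list
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, config_text: str, parameters: dict,
               seed: int | None, outputs: list) -> "RunManifest":
        from . import __version__
        return cls(
            command=command,
            config_hash=hashlib.sha256(config_text.encode()).hexdigest()[:16],
            parameters=parameters,
            seed=seed,
            outputs=[str(p) for p in outputs],
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8")
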