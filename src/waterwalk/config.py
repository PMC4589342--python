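"""Run configuration: a YAML-round-trippable bundle of all module parameters.

A single master seed deterministically derives every module seed, so a whole
experiment is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import yaml

from .landscape import CostTable, SpeedTable, SyntheticLandscapeConfig
from .movement import SimulationParams, WaterChoiceParams
from .pathfinding import SearchParams

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; names the offending key."""


@dataclass
class RunConfig:
    """Everything a run needs: landscape source, search, choice, simulation,
    binning, the sweep axes and a master seed."""

    landscape: SyntheticLandscapeConfig = field(default_factory=SyntheticLandscapeConfig)
    landscape_files: dict | None = None  # {"raster": ..., "villages": ..., "boreholes": ...}
    search: SearchParams = field(default_factory=lambda: SearchParams(g_mode="as_printed"))
    choice: WaterChoiceParams = field(default_factory=WaterChoiceParams)
    sim: SimulationParams = field(default_factory=SimulationParams)
    n_bins: int = 5
    sweep_alphas: tuple[float, ...] = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0)
    sweep_thresholds_km: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    n_repeats: int = 100
    master_seed: int = 0

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed derived from the master seed."""
        digest = hashlib.sha256(f"{self.master_seed}:{module}".encode()).digest()
        return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF

    def with_seeds(self) -> "RunConfig":
        """A copy with every module seed derived from the master seed."""
        return dataclasses.replace(
            self,
            landscape=dataclasses.replace(self.landscape, seed=self.module_seed("landscape")),
            choice=dataclasses.replace(self.choice, seed=self.module_seed("choice")),
            sim=dataclasses.replace(self.sim, seed=self.module_seed("sim")),
        )

    def content_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(_to_plain(self), sort_keys=True).encode()).hexdigest()[:16]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in section {where!r}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {where!r}: {exc}") from exc


_SECTIONS = {
    "landscape": SyntheticLandscapeConfig,
    "search": SearchParams,
    "choice": WaterChoiceParams,
    "sim": SimulationParams,
}
_SCALARS = {"n_bins", "n_repeats", "master_seed", "sweep_alphas", "sweep_thresholds_km", "landscape_files"}


def load_config(path: str | FsPath) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise :class:`ConfigError`."""
    data = yaml.safe_load(FsPath(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown configuration key {sorted(unknown)[0]!r}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name] or {}
            if name == "search" and isinstance(section, dict) and "cost_table" in section:
                section = dict(section)
                section["cost_table"] = _build(CostTable, section["cost_table"] or {}, "cost_table")
            if name == "sim" and isinstance(section, dict) and "speed_table" in section:
                section = dict(section)
                section["speed_table"] = _build(SpeedTable, section["speed_table"] or {}, "speed_table")
            kwargs[name] = _build(cls, section, name)
    for name in _SCALARS:
        if name in data:
            v = data[name]
            kwargs[name] = tuple(v) if isinstance(v, list) else v
    return _build(RunConfig, kwargs, "run")


def save_config(cfg: RunConfig, path: str | FsPath) -> None:
    """Write a configuration as YAML; load_config(save_config(c)) == c."""
    FsPath(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))
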