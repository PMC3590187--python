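"""Validated configuration records shared by every simulation entry point.

All model parameters live in two frozen dataclasses: :class:`GridConfig`
(the lattice) and :class:`SimulationConfig` (lattice + dynamics + run
protocol).  Validation happens eagerly at construction and every error
names the offending field, so a bad parameter never reaches a simulation
loop.  Configs round-trip losslessly through plain dicts and YAML/JSON
files (see :func:`parse_config` / :meth:`SimulationConfig.to_dict`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "GridConfig",
    "SimulationConfig",
    "ConfigError",
    "parse_config",
]


class ConfigError(ValueError):
    """A configuration value violated its documented invariant."""


def _require(cond: bool, name: str, constraint: str, value: Any) -> None:
    if not cond:
        raise ConfigError(f"{name} must satisfy {constraint}, got {value!r}")


@dataclass(frozen=True)
class GridConfig:
    """Square lattice of candidate burrow sites.

    Parameters
    ----------
    L : int
        Lattice width in sites; the grid holds ``L x L`` burrows.
    L_c : int
        Width of the central sub-grid used for boundary-free statistics.
    rho : float
        Occupancy density; ``round(rho * L**2)`` males are placed.
    """

    L: int = 30
    L_c: int = 10
    rho: float = 0.4

    def __post_init__(self) -> None:
        _require(isinstance(self.L, int) and self.L >= 1, "L", "integer >= 1", self.L)
        _require(
            isinstance(self.L_c, int) and 1 <= self.L_c <= self.L,
            "L_c", "integer with 1 <= L_c <= L", self.L_c,
        )
        _require(0.0 < self.rho <= 1.0, "rho", "0 < rho <= 1", self.rho)
        if self.n_individuals == 0:
            raise ConfigError(
                f"rho={self.rho} with L={self.L} rounds to an empty population"
            )

    @property
    def n_individuals(self) -> int:
        """Population size ``round(rho * L**2)`` (nearest-integer rounding)."""
        return int(round(self.rho * self.L * self.L))

    def central_offset(self) -> int:
        """Lower coordinate of the centered ``L_c x L_c`` sub-grid."""
        return (self.L - self.L_c) // 2


_MODELS = ("M1", "M2")
_VARIANTS = ("plain", "distance-weighted")
_FORMS = ("map_of_mean", "mean_of_map")
_TIE_RULES = ("count-random", "similarity")
_BOUNDARY_RULES = ("clip", "literal")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set for one lattice run (or replicate family).

    Defaults follow the reference study conditions: reach ``R = 3`` sites,
    ``L = 30`` lattice, ``L_c = 10`` central sub-grid, attention angle
    ``theta = 60`` degrees, measurement window ``n_l = 500`` steps after a
    ``n_transient = 500``-step transient, and ``s_t = 500`` replicates.
    """

    mu: float = 3.2
    D: float = 0.5
    grid: GridConfig = field(default_factory=GridConfig)
    theta: float = 60.0
    R: float = 3.0
    model: str = "M1"
    n_transient: int = 500
    n_l: int = 500
    s_t: int = 500
    seed: int = 0
    coupling_variant: str = "plain"
    coupling_form: str = "map_of_mean"
    tie_rule: str = "count-random"
    boundary_rule: str = "clip"
    weight_exponent: float = 1.0

    def __post_init__(self) -> None:
        _require(1.0 < self.mu <= 4.0, "mu", "1 < mu <= 4", self.mu)
        _require(0.0 <= self.D <= 1.0, "D", "0 <= D <= 1", self.D)
        _require(0.0 < self.theta <= 360.0, "theta", "0 < theta <= 360", self.theta)
        _require(self.R > 0, "R", "R > 0", self.R)
        _require(self.model in _MODELS, "model", f"one of {_MODELS}", self.model)
        _require(self.n_transient >= 0, "n_transient", "n_transient >= 0", self.n_transient)
        _require(self.n_l >= 2, "n_l", "n_l >= 2", self.n_l)
        _require(self.s_t >= 1, "s_t", "s_t >= 1", self.s_t)
        _require(
            isinstance(self.seed, int) and self.seed >= 0,
            "seed", "non-negative integer", self.seed,
        )
        _require(
            self.coupling_variant in _VARIANTS,
            "coupling_variant", f"one of {_VARIANTS}", self.coupling_variant,
        )
        _require(
            self.coupling_form in _FORMS,
            "coupling_form", f"one of {_FORMS}", self.coupling_form,
        )
        _require(
            self.tie_rule in _TIE_RULES,
            "tie_rule", f"one of {_TIE_RULES}", self.tie_rule,
        )
        _require(
            self.boundary_rule in _BOUNDARY_RULES,
            "boundary_rule", f"one of {_BOUNDARY_RULES}", self.boundary_rule,
        )
        _require(
            self.weight_exponent > 0,
            "weight_exponent", "weight_exponent > 0", self.weight_exponent,
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        grid_known = {f.name for f in dataclasses.fields(GridConfig)}
        payload: dict[str, Any] = {}
        grid_payload: dict[str, Any] = {}
        for key, value in data.items():
            if key in grid_known:  # allow flat L / L_c / rho keys
                grid_payload[key] = value
            elif key == "grid":
                if not isinstance(value, Mapping):
                    raise ConfigError(f"grid must be a mapping, got {value!r}")
                for gk, gv in value.items():
                    if gk not in grid_known:
                        raise ConfigError(f"unknown grid key {gk!r}")
                    grid_payload[gk] = gv
            elif key in known:
                payload[key] = value
            else:
                raise ConfigError(f"unknown configuration key {key!r}")
        payload["grid"] = GridConfig(**{**dataclasses.asdict(GridConfig()), **grid_payload})
        return cls(**payload)

    def replace(self, **changes: Any) -> "SimulationConfig":
        grid_known = {f.name for f in dataclasses.fields(GridConfig)}
        grid_changes = {k: changes.pop(k) for k in list(changes) if k in grid_known}
        grid = dataclasses.replace(self.grid, **grid_changes) if grid_changes else self.grid
        return dataclasses.replace(self, grid=grid, **changes)


def parse_config(
    source: str | Path | Mapping[str, Any] | None = None,
    **overrides: Any,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML/JSON file, dict, or kwargs.

    ``overrides`` win over file values (CLI flags beat config files).  An
    empty source yields all defaults.  Unknown keys, type mismatches and
    invariant violations raise :class:`ConfigError` naming the field.
    """
    data: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, Mapping):
            data.update(source)
        else:
            path = Path(source)
            text = path.read_text()
            loaded = (
                json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
            )
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, Mapping):
                raise ConfigError(f"config file {path} must hold a mapping")
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return SimulationConfig.from_dict(data)
    except TypeError as exc:  # wrong type reaching a dataclass field
        raise ConfigError(str(exc)) from exc
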