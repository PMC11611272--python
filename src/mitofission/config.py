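"""Flat TOML run configuration.

Sections: ``[model]`` (dimensional rate constants and totals),
``[dimensionless]`` (the four groups plus gamma/theta; derived from
``[model]`` when omitted), ``[solver]`` and ``[sensitivity]``. An empty
file reproduces the canonical parameter set (mu resolves to 750).
"""

from __future__ import annotations

import tomllib
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from .params import (
    DimensionalParams,
    DimensionlessParams,
    nondimensionalize,
    params_to_dict,
)

__all__ = ["SolverConfig", "SensitivityConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10
    n_points: int = 2000
    method: str = "LSODA"
    t_end: Optional[float] = None  # None -> system-specific default horizon


@dataclass(frozen=True)
class SensitivityConfig:
    case: str = "case1"
    base_N: int = 2048
    seed: int = 0  # fixed documented default; never time-based
    n_boot: int = 1000


@dataclass(frozen=True)
class RunConfig:
    model: DimensionalParams = field(default_factory=DimensionalParams)
    dimensionless: Optional[DimensionlessParams] = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)

    def resolve_dimensionless(self) -> DimensionlessParams:
        if self.dimensionless is not None:
            return self.dimensionless
        return nondimensionalize(self.model)


_INT_KEYS = {"ell", "N_max", "n_points", "base_N", "seed", "n_boot"}


def _build(section: str, cls, raw: dict, errors: list):
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            warnings.warn(f"[{section}] ignoring unknown key {key!r}",
                          stacklevel=3)
            continue
        if key in _INT_KEYS:
            if value != int(value):
                errors.append(f"[{section}] {key} must be an integer, "
                              f"got {value!r}")
                continue
            value = int(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (ValueError, ZeroDivisionError) as exc:
        errors.append(f"[{section}] {exc}")
        return None


def load_config(path) -> RunConfig:
    """Parse and validate a TOML config; all violations reported at once."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    errors: list[str] = []
    for section in data:
        if section not in ("model", "dimensionless", "solver", "sensitivity"):
            warnings.warn(f"ignoring unknown section [{section}]",
                          stacklevel=2)
    model = _build("model", DimensionalParams, data.get("model", {}), errors)
    dimless = None
    if "dimensionless" in data:
        dimless = _build("dimensionless", DimensionlessParams,
                         data["dimensionless"], errors)
    solver = _build("solver", SolverConfig, data.get("solver", {}), errors)
    sens = _build("sensitivity", SensitivityConfig,
                  data.get("sensitivity", {}), errors)
    if sens is not None and sens.case not in ("case1", "case2",
                                              "dimensionless"):
        errors.append(f"[sensitivity] unknown case {sens.case!r}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(model=model, dimensionless=dimless,
                     solver=solver, sensitivity=sens)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, str):
        return f'"{value}"'
    return repr(value)


def save_config(config: RunConfig, path) -> None:
    """Write a config back to flat TOML (round-trips with load_config)."""
    lines = ["[model]"]
    for k, v in params_to_dict(config.model).items():
        lines.append(f"{k} = {_fmt(v)}")
    if config.dimensionless is not None:
        lines.append("\n[dimensionless]")
        for k, v in params_to_dict(config.dimensionless).items():
            lines.append(f"{k} = {_fmt(v)}")
    lines.append("\n[solver]")
    for f in fields(config.solver):
        v = getattr(config.solver, f.name)
        if v is not None:
            lines.append(f"{f.name} = {_fmt(v)}")
    lines.append("\n[sensitivity]")
    for f in fields(config.sensitivity):
        lines.append(f"{f.name} = {_fmt(getattr(config.sensitivity, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n")
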