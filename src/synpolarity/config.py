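"""YAML configuration: physiological constants, search ranges, GA settings.

Example::

    physio:
      q_s: 0.039
      g_L: 0.0067
    ranges:
      X_o: [0.0, 4.0]
    ga:
      islands: 4
      pool_size: 35
    solver:
      method: hybrid
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .neurodynamics import OPT_RANGES, PhysioParams, SolverConfig
from .optimizer import GAConfig

__all__ = ["load_config", "load_params", "load_ga_config", "load_solver"]


def _read(path) -> dict:
    obj = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(obj, dict):
        raise ValueError(f"config root must be a mapping, got {type(obj).__name__}")
    return obj


def load_params(path) -> PhysioParams:
    return PhysioParams().replace(**_read(path).get("physio", {}))


def load_ga_config(path) -> GAConfig:
    return GAConfig(**_read(path).get("ga", {}))


def load_solver(path) -> SolverConfig:
    return SolverConfig(**_read(path).get("solver", {}))


def load_config(path) -> dict:
    """Load all sections: physio params, optimization ranges, GA, solver."""
    obj = _read(path)
    ranges = dict(OPT_RANGES)
    for k, v in obj.get("ranges", {}).items():
        if k not in ranges:
            raise ValueError(f"unknown optimized parameter {k!r}")
        ranges[k] = (float(v[0]), float(v[1]))
    return {
        "params": PhysioParams().replace(**obj.get("physio", {})),
        "ranges": ranges,
        "ga": GAConfig(**obj.get("ga", {})),
        "solver": SolverConfig(**obj.get("solver", {})),
    }
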