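"""Run configuration: one flat dataclass, YAML round-trip, CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import InvalidSpecError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All settings of a simulation run, with package defaults filled in.

    Dimensional rates (a1..a6, D2) are used only by the ODE mode; the PDE
    mode runs the dimensionless system with (k1, k2).
    """

    # dimensionless model
    k1: float = 1.0
    k2: float = 0.5
    # dimensional model (ODE mode)
    a1: float = 1.0
    a2: float = 1.0
    a3: float = 1.0
    a4: float = 10.0
    a5: float = 0.5
    a6: float = 1.0
    D2: float = 0.0
    u0: float = 1.0
    v0: float = 0.1
    # grid
    L: float = 900.0
    N: int = 256
    # stepping
    dt: float = 0.05
    t_max: float = 400.0
    save_every: int = 20
    dealias: str = "pad"
    # initial condition
    ic: str = "bumps"
    amplitude: float = 1e-3
    seed: int = 0
    # diagnostics
    late_fraction: float = 0.5
    steady_tol: float = 1e-5
    periodic_tol: float = 1e-3

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidSpecError(f"config {path} is not a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved config (all defaults filled) as YAML."""
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
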