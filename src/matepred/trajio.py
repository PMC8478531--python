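"""Trajectory serialization: long-format CSV plus a JSON metadata sidecar.

The CSV has header ``t,x,U,V`` with one row per (sample time, node); in
ODE mode x is 0.  Metadata (parameters, grid, stepping, dealias mode,
seed, diverged flag) goes in ``<path>.meta.json`` so the CSV stays a
plain rectangular table any tool can read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .etdrk4 import Trajectory

__all__ = ["write_trajectory", "read_trajectory"]

_HEADER = ["t", "x", "U", "V"]


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as long CSV + metadata sidecar."""
    path = Path(path)
    n_samples, N = traj.U.shape
    L = float(traj.metadata.get("L", 0.0))
    x = np.arange(N) * (L / N) if (L > 0 and N > 1) else np.zeros(N)
    df = pd.DataFrame(
        {
            "t": np.repeat(traj.t, N),
            "x": np.tile(x, n_samples),
            "U": traj.U.ravel(),
            "V": traj.V.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = dict(traj.metadata)
    meta["diverged"] = bool(traj.diverged)
    _meta_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Raises :class:`ParseError` (with a line number) on a malformed file.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header.split(",") != _HEADER:
        raise ParseError(f"expected header {','.join(_HEADER)!r}, got {header!r}", line=1)
    try:
        df = pd.read_csv(path, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        line = getattr(exc, "lineno", None)
        raise ParseError(f"malformed trajectory CSV: {exc}", line=line) from exc

    times = df["t"].unique()
    N = int((df["t"] == times[0]).sum())
    if len(df) != len(times) * N:
        raise ParseError("ragged trajectory: unequal nodes per sample time")
    U = df["U"].to_numpy().reshape(len(times), N)
    V = df["V"].to_numpy().reshape(len(times), N)

    meta, diverged = {}, False
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
        diverged = bool(meta.pop("diverged", False))
    return Trajectory(t=times, U=U, V=V, metadata=meta, diverged=diverged)
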