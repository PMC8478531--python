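"""Long-time regime classification and convergence diagnostics.

The classification signal is the spatial mean of the predator field V:
mode-0 dynamics distinguishes a run that settles onto a homogeneous
steady state from one that sustains oscillations, and is insensitive to
where spatial features sit on the periodic domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, NoPeriodError
from .etdrk4 import Trajectory, integrate
from .model import DimensionlessParams
from .spectral import make_grid

__all__ = [
    "RegimeReport",
    "classify_regime",
    "estimate_period",
    "convergence_order",
    "sweep_k2",
]

EXTINCTION_TOL = 1e-6
#: relative spread of successive inter-peak intervals accepted as periodic
PEAK_SPACING_SPREAD = 0.05


@dataclass(frozen=True)
class RegimeReport:
    """Classification of a trajectory's long-time behavior.

    ``label`` is one of steady, periodic, decaying-to-extinction,
    diverging, undetermined.  ``amplitude`` is the late-window
    peak-to-peak range of spatial-mean V; ``period`` is set only for the
    periodic label.  ``window`` is the (t_start, t_end) of the samples
    the decision used.
    """

    label: str
    final_mean_U: float
    final_mean_V: float
    amplitude: float
    period: float | None
    window: tuple[float, float]


def _interior_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict 3-point local maxima, refined parabolically.

    Returns fractional sample positions of each interior maximum.
    """
    i = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
    if i.size == 0:
        return np.empty(0)
    # parabola through (i-1, i, i+1): vertex offset in samples
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    off = np.where(np.abs(denom) > 0, 0.5 * (y[i - 1] - y[i + 1]) / np.where(denom == 0, 1.0, denom), 0.0)
    return i + off


def estimate_period(signal: np.ndarray, dt: float) -> float:
    """Mean spacing of successive interior maxima of a uniformly sampled signal.

    Maxima are located by 3-point comparison and refined by fitting a
    parabola through each triple.  Requires at least three interior
    maxima.
    """
    signal = np.asarray(signal, dtype=float)
    peaks = _interior_maxima(signal)
    if peaks.size < 3:
        raise NoPeriodError(f"need >= 3 interior maxima, found {peaks.size}")
    return float(np.mean(np.diff(peaks)) * dt)


def classify_regime(
    traj: Trajectory,
    late_fraction: float = 0.5,
    steady_tol: float = 1e-5,
    periodic_tol: float = 1e-3,
) -> RegimeReport:
    """Classify the long-time behavior of a trajectory.

    On the trailing ``late_fraction`` of samples of spatial-mean V:
    peak-to-peak range below ``steady_tol`` means steady; range above
    ``periodic_tol`` with at least three near-equal successive inter-peak
    intervals (relative spread < 5%) means periodic.  A diverged run is
    labelled diverging, final means below 1e-6 decaying-to-extinction,
    anything else undetermined.
    """
    if traj.n_samples < 50:
        raise InsufficientDataError(
            f"need >= 50 samples to classify, got {traj.n_samples}"
        )
    v = traj.mean_V
    u = traj.mean_U
    start = int(math.floor(len(v) * (1.0 - late_fraction)))
    start = min(max(start, 0), len(v) - 2)
    late_v = v[start:]
    late_t = traj.t[start:]
    window = (float(late_t[0]), float(late_t[-1]))
    amplitude = float(np.max(late_v) - np.min(late_v))
    final = (float(u[-1]), float(v[-1]))

    if traj.diverged:
        return RegimeReport("diverging", *final, amplitude, None, window)
    if abs(final[0]) < EXTINCTION_TOL and abs(final[1]) < EXTINCTION_TOL:
        return RegimeReport("decaying-to-extinction", *final, amplitude, None, window)
    if amplitude < steady_tol:
        return RegimeReport("steady", *final, amplitude, None, window)
    if amplitude > periodic_tol:
        peaks = _interior_maxima(late_v)
        if peaks.size >= 4:  # >= 3 successive intervals
            gaps = np.diff(peaks)
            if np.max(gaps) - np.min(gaps) < PEAK_SPACING_SPREAD * np.mean(gaps):
                dt_s = float(np.mean(np.diff(late_t)))
                period = float(np.mean(gaps) * dt_s)
                return RegimeReport("periodic", *final, amplitude, period, window)
    return RegimeReport("undetermined", *final, amplitude, None, window)


def convergence_order(
    run: Callable[[float], np.ndarray],
    dt_list: Sequence[float],
    roundoff_floor: float = 1e-13,
) -> pd.DataFrame:
    """Richardson order estimates for a fixed-step integrator.

    ``run(dt)`` must return the solution (any flat array) at a common
    final time.  ``dt_list`` must contain at least three step sizes, each
    half the previous; the reference solution is run at the smallest
    step divided by 8.  Errors are max-norm against the reference;
    orders are log2(e_i / e_{i+1}).  Pairs whose errors sit below the
    roundoff floor are flagged not estimable (order set to NaN).
    """
    dts = [float(d) for d in dt_list]
    if len(dts) < 3:
        raise InsufficientDataError("need at least three step sizes")
    for a, b in zip(dts, dts[1:]):
        if not math.isclose(b, a / 2.0, rel_tol=1e-12):
            raise InsufficientDataError("each dt must be half the previous")
    ref = np.asarray(run(dts[-1] / 8.0), dtype=float).ravel()
    errs = [
        float(np.max(np.abs(np.asarray(run(d), dtype=float).ravel() - ref)))
        for d in dts
    ]
    rows = []
    for i in range(len(dts) - 1):
        estimable = errs[i] > roundoff_floor and errs[i + 1] > roundoff_floor
        order = math.log2(errs[i] / errs[i + 1]) if estimable else math.nan
        rows.append(
            {"dt": dts[i], "error": errs[i], "order": order, "estimable": estimable}
        )
    rows.append(
        {"dt": dts[-1], "error": errs[-1], "order": math.nan, "estimable": False}
    )
    return pd.DataFrame(rows)


def sweep_k2(
    k2_values: Sequence[float],
    *,
    k1: float = 1.0,
    initial_condition: Callable | None = None,
    L: float = 900.0,
    N: int = 256,
    dt: float = 0.05,
    t_max: float = 400.0,
    save_every: int = 20,
    dealias: str = "pad",
    late_fraction: float = 0.5,
    steady_tol: float = 1e-5,
    periodic_tol: float = 1e-3,
) -> pd.DataFrame:
    """Classify one run per k2 value; deterministic given settings.

    ``initial_condition(grid)`` must return (U0, V0); the default is the
    quadratic-bump / linear-ramp fixture.  Returns a table with columns
    k2, label, period, amplitude, final_meanU, final_meanV.  The table's
    ``attrs`` record the smallest k2 classified steady and the largest
    classified periodic (None when absent).
    """
    from .initial_conditions import bump_initial_condition  # avoid import cycle

    g = make_grid(L, N)
    if initial_condition is None:
        initial_condition = bump_initial_condition
    rows = []
    for k2 in k2_values:
        try:
            k = DimensionlessParams(k1=k1, k2=float(k2))
            U0, V0 = initial_condition(g)
            traj = integrate(
                U0, V0, g, k, dt=dt, t_max=t_max, save_every=save_every, dealias=dealias
            )
            rep = classify_regime(traj, late_fraction, steady_tol, periodic_tol)
            rows.append(
                {
                    "k2": float(k2), "label": rep.label,
                    "period": rep.period if rep.period is not None else math.nan,
                    "amplitude": rep.amplitude,
                    "final_meanU": rep.final_mean_U, "final_meanV": rep.final_mean_V,
                }
            )
        except Exception:
            rows.append(
                {
                    "k2": float(k2), "label": "undetermined", "period": math.nan,
                    "amplitude": math.nan, "final_meanU": math.nan,
                    "final_meanV": math.nan,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["k2", "label", "period", "amplitude", "final_meanU", "final_meanV"],
    )
    steady = table.loc[table.label == "steady", "k2"]
    periodic = table.loc[table.label == "periodic", "k2"]
    table.attrs["smallest_steady_k2"] = float(steady.min()) if len(steady) else None
    table.attrs["largest_periodic_k2"] = float(periodic.max()) if len(periodic) else None
    return table
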