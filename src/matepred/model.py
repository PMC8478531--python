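"""Prey–predator model with a mating-pair predation term.

Two forms of the model are supported.  The dimensional form

    u_t = a1*u - a2*u^2 - a3*u*v - a4*u*v^2
    v_t = D2*v_xx + a3*u*v - a5*v - a6*v^2 + a4*u*v^2

describes prey ``u`` and predator ``v`` with logistic prey growth,
single-predator predation (a3) and predation by a mating pair of
predators (a4, the model's distinguishing term).  Rescaling reduces the
reaction part to the two-parameter dimensionless form

    U_t = U - U^2 - U*V - U*V^2
    V_t = V_XX - k1*k2*V - k1*V^2 + k1*U*V + k1*U*V^2

with k1 = a3/a2 and k2 = a5/(a1*k1).

This module holds the parameter containers, the reaction terms, the
nondimensionalization map, equilibria of the homogeneous (well-mixed)
dimensionless system, their Jacobians, and the dispersion relation used
for linear stability of spatial perturbations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import DimensionError, InvalidParameterError

__all__ = [
    "DimensionalParams",
    "DimensionlessParams",
    "Equilibrium",
    "EquilibriumSet",
    "nondimensionalize",
    "reaction_dimensional",
    "reaction_dimensionless",
    "find_equilibria",
    "jacobian",
    "dispersion_relation",
    "STABILITY_EIGENVALUE_TOL",
]

#: |Re lambda| below this is labelled "marginal" rather than stable/unstable.
STABILITY_EIGENVALUE_TOL = 1e-9

#: residual bound every reported equilibrium must satisfy
EQUILIBRIUM_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class DimensionalParams:
    """Rates of the dimensional model.

    Parameters
    ----------
    a1 : float
        Prey growth rate (1/time). Strictly positive.
    a2 : float
        Prey intraspecific decay rate. Strictly positive.
    a3 : float
        One-predator predation rate. Nonnegative.
    a4 : float
        Mating-pair (two predators, one prey) predation rate. Nonnegative.
    a5 : float
        Predator mortality rate. Nonnegative.
    a6 : float
        Predator intraspecific decay rate. Nonnegative.
    D2 : float
        Predator diffusion coefficient (length^2/time). Nonnegative.
    """

    a1: float
    a2: float
    a3: float = 0.0
    a4: float = 0.0
    a5: float = 0.0
    a6: float = 0.0
    D2: float = 0.0

    def __post_init__(self):
        vals = (self.a1, self.a2, self.a3, self.a4, self.a5, self.a6, self.D2)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("all rates must be finite")
        if self.a1 <= 0 or self.a2 <= 0:
            raise InvalidParameterError("a1 and a2 must be strictly positive")
        if min(self.a3, self.a4, self.a5, self.a6, self.D2) < 0:
            raise InvalidParameterError("a3..a6 and D2 must be nonnegative")


@dataclass(frozen=True)
class DimensionlessParams:
    """Parameters of the dimensionless model: interaction strength ``k1 > 0``
    and scaled predator mortality ``k2 >= 0``."""

    k1: float
    k2: float

    def __post_init__(self):
        if not (math.isfinite(self.k1) and math.isfinite(self.k2)):
            raise InvalidParameterError("k1, k2 must be finite")
        if self.k1 <= 0:
            raise InvalidParameterError("k1 must be strictly positive")
        if self.k2 < 0:
            raise InvalidParameterError("k2 must be nonnegative")


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Map dimensional rates to the dimensionless pair (k1, k2).

    The operative definition is ``k1 = a3/a2`` and ``k2 = a5/(a1*k1)``.
    An alternative reading of the rescaling, ``k1 = sqrt(a4*a1)/a2``, is
    evaluated as a consistency check; a RuntimeWarning is emitted when the
    two disagree by more than 1e-9 relative, which signals that the given
    rates do not satisfy the constraint tying a3 and a4 together.
    """
    if p.a3 <= 0:
        raise InvalidParameterError("nondimensionalization requires a3 > 0")
    k1 = p.a3 / p.a2
    k1_alt = math.sqrt(p.a4 * p.a1) / p.a2
    if abs(k1_alt - k1) > 1e-9 * max(abs(k1), 1e-300):
        warnings.warn(
            f"a4-based expression for k1 ({k1_alt:.6g}) disagrees with "
            f"a3/a2 ({k1:.6g}); using k1 = a3/a2",
            RuntimeWarning,
            stacklevel=2,
        )
    return DimensionlessParams(k1=k1, k2=p.a5 / (p.a1 * k1))


def _check_shapes(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(f"shape mismatch: {u.shape} vs {v.shape}")
    return u, v


def reaction_dimensional(u, v, p: DimensionalParams):
    """Reaction parts (du/dt, dv/dt) of the dimensional model.

    Diffusion is not included; it is handled spectrally by the solver.
    """
    u, v = _check_shapes(u, v)
    du = p.a1 * u - p.a2 * u**2 - p.a3 * u * v - p.a4 * u * v**2
    dv = p.a3 * u * v - p.a5 * v - p.a6 * v**2 + p.a4 * u * v**2
    return du, dv


def reaction_dimensionless(U, V, k: DimensionlessParams):
    """Reaction parts (dU/dt, dV/dt) of the dimensionless model.

    Diffusion (V_XX) is not included here.
    """
    U, V = _check_shapes(U, V)
    dU = U - U**2 - U * V - U * V**2
    dV = k.k1 * (-k.k2 * V - V**2 + U * V + U * V**2)
    return dU, dV


def jacobian(U: float, V: float, k: DimensionlessParams) -> np.ndarray:
    """2x2 Jacobian of the dimensionless reaction terms at a point.

    Analytic partial derivatives; validated against central finite
    differences in the test suite.
    """
    j11 = 1.0 - 2.0 * U - V - V**2
    j12 = -U - 2.0 * U * V
    j21 = k.k1 * (V + V**2)
    j22 = k.k1 * (-k.k2 - 2.0 * V + U + 2.0 * U * V)
    return np.array([[j11, j12], [j21, j22]], dtype=float)


@dataclass(frozen=True)
class Equilibrium:
    """A homogeneous steady state of the dimensionless reaction system."""

    U: float
    V: float
    kind: str  # "extinction" | "prey-only" | "coexistence"
    stability: str  # "stable" | "unstable" | "marginal"
    eigenvalues: tuple = ()

    @property
    def is_coexistence(self) -> bool:
        return self.kind == "coexistence"


@dataclass(frozen=True)
class EquilibriumSet:
    """All homogeneous equilibria for one parameter pair."""

    params: DimensionlessParams
    equilibria: tuple[Equilibrium, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.equilibria)

    def __len__(self):
        return len(self.equilibria)

    @property
    def coexistence(self) -> tuple[Equilibrium, ...]:
        return tuple(e for e in self.equilibria if e.is_coexistence)

    @property
    def extinction(self) -> Equilibrium:
        return next(e for e in self.equilibria if e.kind == "extinction")

    @property
    def prey_only(self) -> Equilibrium:
        return next(e for e in self.equilibria if e.kind == "prey-only")


def _stability_label(eigs) -> str:
    re = np.real(eigs)
    if np.any(np.abs(re) < STABILITY_EIGENVALUE_TOL):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


def _classify(U, V, k, kind) -> Equilibrium:
    eigs = np.linalg.eigvals(jacobian(U, V, k))
    return Equilibrium(
        U=float(U),
        V=float(V),
        kind=kind,
        stability=_stability_label(eigs),
        eigenvalues=tuple(complex(e) for e in eigs),
    )


def _residual(U, V, k) -> float:
    dU, dV = reaction_dimensionless(float(U), float(V), k)
    return max(abs(float(dU)), abs(float(dV)))


def find_equilibria(k: DimensionlessParams) -> EquilibriumSet:
    """All homogeneous equilibria of the dimensionless system.

    Always contains extinction (0,0) and prey-only (1,0).  Interior
    (coexistence) states solve 1 - U - V - V^2 = 0 together with
    U + U*V - k2 - V = 0 (the k1 factor drops out); substituting
    U = 1 - V - V^2 into the second equation reduces the system to the
    cubic

        V^3 + 2*V^2 + V + (k2 - 1) = 0,

    which is strictly increasing for V > 0 and therefore has exactly one
    positive root iff k2 < 1.  Candidate roots are bracketed by sign
    change on V in (0, 5], polished with a damped Newton iteration on the
    full 2-D system, and accepted only if U, V > 0 and the reaction
    residual is at most 1e-10.
    """
    out = [_classify(0.0, 0.0, k, "extinction"), _classify(1.0, 0.0, k, "prey-only")]

    cubic = np.polynomial.Polynomial([k.k2 - 1.0, 1.0, 2.0, 1.0])
    vgrid = np.linspace(0.0, 5.0, 2001)
    fv = cubic(vgrid)
    for i in np.flatnonzero(np.sign(fv[:-1]) * np.sign(fv[1:]) < 0):
        v0 = optimize.brentq(cubic, vgrid[i], vgrid[i + 1], xtol=1e-14)
        u0 = 1.0 - v0 - v0**2
        if u0 <= 0 or v0 <= 0:
            continue
        sol = optimize.root(
            lambda x: np.array(reaction_dimensionless(x[0], x[1], k)),
            x0=[u0, v0],
            jac=lambda x: jacobian(x[0], x[1], k),
            method="hybr",
            tol=1e-14,
        )
        U, V = (sol.x if sol.success else (u0, v0))
        if U > 0 and V > 0 and _residual(U, V, k) <= EQUILIBRIUM_RESIDUAL_TOL:
            out.append(_classify(U, V, k, "coexistence"))
    return EquilibriumSet(params=k, equilibria=tuple(out))


def dispersion_relation(eq, k: DimensionlessParams, q) -> np.ndarray:
    """Growth-rate eigenvalues of a homogeneous equilibrium at wavenumber q.

    For a perturbation ~ exp(i*q*X) about (U*, V*), the linearized system
    has matrix J(U*, V*) - diag(0, q^2): only the predator diffuses, so
    diffusion damps only the V component.  Returns the two eigenvalues
    for each requested q (shape (..., 2), sorted by descending real part).

    Raises
    ------
    InvalidParameterError
        If (U*, V*) is not an equilibrium (reaction residual > 1e-8).
    """
    if isinstance(eq, Equilibrium):
        U, V = eq.U, eq.V
    else:
        U, V = float(eq[0]), float(eq[1])
    if _residual(U, V, k) > 1e-8:
        raise InvalidParameterError(
            f"({U}, {V}) is not an equilibrium (residual > 1e-8)"
        )
    J = jacobian(U, V, k)
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    out = np.empty(q.shape + (2,), dtype=complex)
    for idx, qi in np.ndenumerate(q):
        A = J.copy()
        A[1, 1] -= qi**2
        eigs = np.linalg.eigvals(A)
        out[idx] = eigs[np.argsort(-eigs.real)]
    return out[0] if scalar else out
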