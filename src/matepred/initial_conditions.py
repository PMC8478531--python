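"""Initial-condition fixtures.

Two generator families:

* ``bump_initial_condition`` — the published benchmark data for the
  dimensionless system on a domain of length 900: a shallow quadratic
  bump in the prey field,

      U0(x) = bU - cU*(x - r1)*(x - r2),

  and a gentle linear ramp plus offset in the predator field,

      V0(x) = bV - cV*(x - r3) + dV.

  The printed source of these fields is typographically corrupted, so
  the family is fully parameterized: any alternative reading is
  reachable through :class:`InitialConditionSpec` without code changes.

* ``perturbed_homogeneous`` — a homogeneous state plus a seeded smooth
  perturbation built from the three lowest nonzero cosine modes,
  for controlled linear-stability experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError
from .spectral import Grid1D

__all__ = [
    "InitialConditionSpec",
    "bump_initial_condition",
    "perturbed_homogeneous",
    "DEFAULT_BUMP_SPEC",
]


@dataclass(frozen=True)
class InitialConditionSpec:
    """Parameters of an initial-condition family.

    ``kind`` is one of "bumps", "homogeneous-plus-noise", "custom-table".
    For "bumps": base levels ``bU``/``bV``, quadratic coefficient ``cU``
    with roots ``r1``/``r2``, linear coefficient ``cV`` centred at ``r3``,
    and offset ``dV``.  For the stochastic kind: ``base`` state,
    perturbation ``amplitude`` and ``seed``.
    """

    kind: str = "bumps"
    bU: float = 6.0 / 35.0
    cU: float = 2e-7
    r1: float = 225.0
    r2: float = 675.0
    bV: float = 116.0 / 245.0
    cV: float = 3e-5
    r3: float = 450.0
    dV: float = 1.8e-4
    base: tuple[float, float] = (1.0, 0.1)
    amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("bumps", "homogeneous-plus-noise", "custom-table"):
            raise InvalidSpecError(f"unknown initial-condition kind {self.kind!r}")


DEFAULT_BUMP_SPEC = InitialConditionSpec()


def bump_initial_condition(
    g: Grid1D, spec: InitialConditionSpec = DEFAULT_BUMP_SPEC
):
    """Evaluate the quadratic-bump / linear-ramp fields on a grid.

    With the default coefficients (meant for L = 900):
    U0 = 6/35 - 2e-7*(x-225)*(x-675), V0 = 116/245 - 3e-5*(x-450) + 1.8e-4.
    Both fields must come out strictly positive on the grid.
    """
    x = g.x
    U0 = spec.bU - spec.cU * (x - spec.r1) * (x - spec.r2)
    V0 = spec.bV - spec.cV * (x - spec.r3) + spec.dV
    if np.min(U0) <= 0 or np.min(V0) <= 0:
        raise InvalidSpecError(
            "initial-condition spec produces nonpositive population fields"
        )
    return U0, V0


def perturbed_homogeneous(
    g: Grid1D, base: tuple[float, float], amplitude: float, seed: int = 0
):
    """Homogeneous state plus a seeded smooth perturbation.

    The perturbation is a superposition of the three lowest nonzero
    cosine modes with coefficients drawn from a seeded generator, then
    rescaled so each field's maximum deviation equals ``amplitude``.
    Deterministic per seed; ``amplitude`` must stay below min(base) so
    the fields remain positive.
    """
    Ub, Vb = float(base[0]), float(base[1])
    if amplitude < 0:
        raise InvalidSpecError("amplitude must be nonnegative")
    if amplitude >= min(Ub, Vb) and amplitude > 0:
        raise InvalidSpecError("amplitude must be smaller than min(base)")
    U0 = np.full(g.N, Ub)
    V0 = np.full(g.N, Vb)
    if amplitude == 0:
        return U0, V0
    rng = np.random.default_rng(seed)
    phase = 2.0 * np.pi * g.x / g.L
    for target in (U0, V0):
        pert = np.zeros(g.N)
        for m in (1, 2, 3):
            coef, shift = rng.uniform(-1, 1), rng.uniform(0, 2 * np.pi)
            pert += coef * np.cos(m * phase + shift)
        target += pert * (amplitude / np.max(np.abs(pert)))
    return U0, V0
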