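"""Periodic 1-D Fourier pseudospectral discretization.

Fields live on an equispaced periodic grid; derivatives act diagonally in
Fourier space, nonlinear products are formed pointwise in physical space
(the pseudospectral rule).  The semi-discrete dimensionless system is

    d/dt u_hat_m = c_U,m * u_hat_m + F_hat_m,    c_U,m = 1
    d/dt v_hat_m = c_V,m * v_hat_m + G_hat_m,    c_V,m = -q_m^2 - k1*k2

with nonlinear forcings

    F = fft(-U^2 - U*V - U*V^2)
    G = k1 * fft(-V^2 + U*V + U*V^2).

Transform convention: forward `numpy.fft.fft` is unnormalized, the inverse
carries 1/N.  The nonlinearity is cubic, so the default dealiasing rule is
zero-padding to 4N with the Nyquist coefficient split across the +N/2 and
-N/2 slots: triple products of retained modes reach wavenumber 3N/2 < 2N,
so on the padded grid nothing wraps and the truncated result is the exact
Galerkin projection of the nonlinearity.  Keeping the Nyquist mode in the
products matters here: the prey equation has no diffusion, its linear
symbol amplifies every mode equally, and only the nonlinear feedback
(-2*U*delta near U = 1) damps sawtooth content — excluding the Nyquist
mode from the products leaves it growing like e^t from roundoff.  The 2/3
truncation rule (exact only for quadratic terms) is available as
``"twothirds"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, NumericsError

__all__ = [
    "Grid1D",
    "SpectralState",
    "make_grid",
    "to_spectral",
    "to_physical",
    "linear_symbols",
    "nonlinear_terms",
    "DEALIAS_MODES",
]

DEALIAS_MODES = ("pad", "twothirds", "none")

#: tolerated imaginary residue (relative to field scale) after an inverse transform
IMAG_RESIDUE_TOL = 1e-8


@dataclass(frozen=True)
class Grid1D:
    """Periodic grid on [0, L) with N equispaced nodes.

    ``x[j] = j*L/N`` and wavenumbers ``q[m] = 2*pi*m/L`` in standard FFT
    ordering (m = 0..N/2, -N/2+1..-1).
    """

    L: float
    N: int
    x: np.ndarray = field(repr=False, compare=False, default=None)
    q: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "x", np.arange(self.N) * (self.L / self.N))
        object.__setattr__(
            self, "q", 2.0 * np.pi * np.fft.fftfreq(self.N, d=self.L / self.N)
        )


def make_grid(L: float, N: int) -> Grid1D:
    """Build a periodic grid; N must be even and at least 8, L positive."""
    if not (isinstance(N, (int, np.integer)) and N >= 8 and N % 2 == 0):
        raise GridError(f"N must be an even integer >= 8, got {N!r}")
    if not (np.isfinite(L) and L > 0):
        raise GridError(f"L must be positive and finite, got {L!r}")
    return Grid1D(L=float(L), N=int(N))


@dataclass
class SpectralState:
    """Spectral coefficients of the two fields at one time."""

    u_hat: np.ndarray
    v_hat: np.ndarray
    t: float = 0.0

    def conjugate_symmetry_defect(self) -> float:
        """Max relative deviation from the conjugate symmetry of a real field."""
        d = 0.0
        for h in (self.u_hat, self.v_hat):
            scale = max(float(np.max(np.abs(h))), 1e-300)
            d = max(d, float(np.max(np.abs(h - np.conj(np.roll(h[::-1], 1))))) / scale)
        return d


def to_spectral(U: np.ndarray, V: np.ndarray, t: float = 0.0) -> SpectralState:
    """Forward-transform real physical fields."""
    return SpectralState(u_hat=np.fft.fft(U), v_hat=np.fft.fft(V), t=t)


def _real_field(f_hat: np.ndarray) -> np.ndarray:
    f = np.fft.ifft(f_hat)
    # floor of 1 on the scale: a field decaying to zero must not trip the
    # check on roundoff-level imaginary parts
    scale = max(float(np.max(np.abs(f))), 1.0)
    if float(np.max(np.abs(f.imag))) > IMAG_RESIDUE_TOL * scale:
        raise NumericsError(
            "imaginary residue after inverse transform exceeds tolerance "
            "(symptom of instability or a non-real spectral state)"
        )
    return f.real


def to_physical(s: SpectralState):
    """Inverse-transform to real physical fields (U, V)."""
    return _real_field(s.u_hat), _real_field(s.v_hat)


def linear_symbols(g: Grid1D, k) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode linear coefficients (c_U, c_V) of the semi-discrete system.

    c_U = 1 for every mode (the +U growth term; prey does not diffuse);
    c_V = -q^2 - k1*k2 (predator diffusion plus scaled mortality).  c_V is
    real and strictly decreasing in |q|.
    """
    c_u = np.ones(g.N)
    c_v = -(g.q**2) - k.k1 * k.k2
    return c_u, c_v


def _pad(f_hat: np.ndarray, N: int, Np: int) -> np.ndarray:
    """Zero-pad spectrum from N to Np modes, scaling so physical values match.

    The coarse Nyquist coefficient represents the cosine mode at N/2; it is
    split evenly between the +N/2 and -N/2 slots of the fine spectrum,
    which keeps the fine field real and equal to the trig interpolant.
    """
    out = np.zeros(Np, dtype=complex)
    h = N // 2
    out[:h] = f_hat[:h]
    out[Np - h + 1 :] = f_hat[h + 1 :]
    out[h] = 0.5 * f_hat[h]
    out[Np - h] = 0.5 * f_hat[h]
    return out * (Np / N)


def _truncate(f_hat: np.ndarray, N: int, Np: int) -> np.ndarray:
    """Galerkin projection back to N modes; +N/2 and -N/2 recombine into
    the coarse Nyquist slot."""
    out = np.zeros(N, dtype=complex)
    h = N // 2
    out[:h] = f_hat[:h]
    out[h + 1 :] = f_hat[Np - h + 1 :]
    out[h] = f_hat[h] + f_hat[Np - h]
    return out * (N / Np)


def nonlinear_terms(
    s: SpectralState, g: Grid1D, k, dealias: str = "pad"
) -> tuple[np.ndarray, np.ndarray]:
    """Spectral nonlinear forcings (F_hat, G_hat) of the semi-discrete system.

    Inverse-transforms the state, forms F = -U^2 - U*V - U*V^2 and
    G = k1*(-V^2 + U*V + U*V^2) pointwise, forward-transforms, and applies
    the selected dealiasing rule.  Conjugate symmetry of real fields is
    preserved by construction.
    """
    if dealias not in DEALIAS_MODES:
        raise ValueError(f"dealias must be one of {DEALIAS_MODES}, got {dealias!r}")
    if not (np.all(np.isfinite(s.u_hat)) and np.all(np.isfinite(s.v_hat))):
        raise NumericsError("non-finite spectral coefficients")

    if dealias == "pad":
        Np = 4 * g.N
        U = _real_field(_pad(s.u_hat, g.N, Np))
        V = _real_field(_pad(s.v_hat, g.N, Np))
    else:
        U = _real_field(s.u_hat)
        V = _real_field(s.v_hat)

    F = -(U**2) - U * V - U * V**2
    G = k.k1 * (-(V**2) + U * V + U * V**2)
    F_hat, G_hat = np.fft.fft(F), np.fft.fft(G)

    if dealias == "pad":
        F_hat = _truncate(F_hat, g.N, Np)
        G_hat = _truncate(G_hat, g.N, Np)
    elif dealias == "twothirds":
        mask = np.abs(g.q) <= (2.0 / 3.0) * np.max(np.abs(g.q))
        F_hat = F_hat * mask
        G_hat = G_hat * mask
    return F_hat, G_hat
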