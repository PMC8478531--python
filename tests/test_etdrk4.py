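"""ETDRK4 coefficients, stepping, and the two integration drivers."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

import matepred as mp
from matepred.errors import BlowUpError, InvalidParameterError


# ---------------------------------------------------------------- coefficients

def _series_oracle(n_terms=6):
    """Taylor polynomials of the four coefficient fractions about z = 0,
    built symbolically — the independent oracle for the cancellation regime."""
    z = sp.symbols("z")
    exprs = {
        "Q": (sp.exp(z / 2) - 1) / z,
        "alpha": (-4 - z + sp.exp(z) * (4 - 3 * z + z**2)) / z**3,
        "beta": 2 * (2 + z + sp.exp(z) * (z - 2)) / z**3,
        "gamma": (-4 - 3 * z - z**2 + sp.exp(z) * (4 - z)) / z**3,
    }
    polys = {}
    for name, e in exprs.items():
        s = sp.series(e, z, 0, n_terms).removeO()
        polys[name] = sp.lambdify(z, s, "numpy")
    return polys


SERIES = _series_oracle()


def test_coefficient_limits_at_zero_match_series_oracle():
    """As c -> 0 the scheme degenerates to classical RK4 quadrature:
    Q -> dt/2, alpha -> dt/6, beta -> dt/3, gamma -> dt/6."""
    dt = 0.1
    co = mp.etd_coefficients(np.array([0.0]), dt)
    assert co.Q[0] == pytest.approx(dt / 2, rel=1e-12)
    assert co.alpha[0] == pytest.approx(dt / 6, rel=1e-12)
    assert co.beta[0] == pytest.approx(dt / 3, rel=1e-12)
    assert co.gamma[0] == pytest.approx(dt / 6, rel=1e-12)
    # and the series oracle agrees with those limits by construction
    assert SERIES["Q"](0.0) * dt == pytest.approx(dt / 2)
    assert SERIES["alpha"](0.0) * dt == pytest.approx(dt / 6)


@pytest.mark.parametrize("z", [1e-8, -1e-6, 1e-4, -1e-3, 1e-2])
def test_contour_averaging_matches_series_in_cancellation_regime(z):
    dt = 1.0
    co = mp.etd_coefficients(np.array([z]), dt)
    for name, attr in [("Q", co.Q), ("alpha", co.alpha), ("beta", co.beta), ("gamma", co.gamma)]:
        expected = float(SERIES[name](z)) * dt
        assert attr[0] == pytest.approx(expected, rel=1e-10), name


@pytest.mark.parametrize("z", [1.0, -2.5, 10.0, 1.0 + 2.0j])
def test_contour_averaging_matches_direct_formulas_at_large_z(z):
    """Above the cancellation regime the direct formulas are well
    conditioned; forcing the contour evaluation must agree to 1e-10."""
    dt = 1.0
    direct = mp.etd_coefficients(np.array([z]), dt, threshold=0.0)
    contour = mp.etd_coefficients(np.array([z]), dt, threshold=np.inf)
    for a, b in zip(
        (direct.Q, direct.alpha, direct.beta, direct.gamma),
        (contour.Q, contour.alpha, contour.beta, contour.gamma),
    ):
        assert abs(a[0] - b[0]) <= 1e-10 * max(abs(a[0]), 1.0)


def test_coefficients_real_for_real_symbol_and_E_is_exponential():
    co = mp.etd_coefficients(np.array([-1.0]), 0.1)
    assert not np.iscomplexobj(co.E)
    assert co.E[0] == pytest.approx(np.exp(-0.1), rel=1e-14)
    assert co.E2[0] == pytest.approx(np.exp(-0.05), rel=1e-14)


def test_coefficients_reject_bad_step():
    with pytest.raises(InvalidParameterError):
        mp.etd_coefficients(np.array([1.0]), 0.0)
    with pytest.raises(InvalidParameterError):
        mp.etd_coefficients(np.array([1.0]), -0.1)


# ------------------------------------------------------------------- stepping

def _zero_forcing(u, v, t):
    return np.zeros_like(u), np.zeros_like(v)


def test_pure_linear_step_is_exact():
    c = np.array([-3.0, -1.0, 0.5, 2.0])
    dt = 0.07
    co = mp.etd_coefficients(c, dt)
    s = mp.SpectralState(
        u_hat=np.array([1.0, 2.0, -1.0, 0.3], dtype=complex),
        v_hat=np.array([0.5, -0.5, 1.0, 1.0], dtype=complex),
    )
    for _ in range(20):
        s = mp.etdrk4_step(s, co, co, _zero_forcing)
    exact = np.exp(c * 20 * dt)
    assert np.max(np.abs(s.u_hat - np.array([1.0, 2.0, -1.0, 0.3]) * exact)) <= 1e-12 * np.max(np.abs(exact))


def test_equilibrium_state_is_a_fixed_point(grid900, k_half):
    N = grid900.N
    U0, V0 = np.ones(N), np.zeros(N)
    traj = mp.integrate(U0, V0, grid900, k_half, dt=0.05, t_max=10.0, save_every=20)
    assert not traj.diverged
    assert np.max(np.abs(traj.U - 1.0)) <= 1e-10
    assert np.max(np.abs(traj.V)) <= 1e-10


def test_single_step_matches_adaptive_reference_to_fifth_order():
    """Scalar forced problem y' = c*y + cos(t), c = -2: one ETDRK4 step has
    local error O(dt^5), checked against a tight adaptive reference."""
    c = -2.0

    def forcing(u, v, t):
        return np.array([np.cos(t)]), np.zeros(1)

    errs = []
    for dt in (0.1, 0.05):
        co = mp.etd_coefficients(np.array([c]), dt)
        co0 = mp.etd_coefficients(np.array([0.0]), dt)
        s = mp.SpectralState(np.array([1.0 + 0j]), np.zeros(1, dtype=complex), t=0.0)
        s = mp.etdrk4_step(s, co, co0, forcing)
        ref = solve_ivp(
            lambda t, y: c * y + np.cos(t), [0, dt], [1.0], rtol=1e-12, atol=1e-14
        ).y[0, -1]
        errs.append(abs(s.u_hat[0].real - ref))
    assert errs[0] < 5e-7
    order = np.log2(errs[0] / errs[1])
    assert 4.5 <= order <= 5.5


def test_blow_up_is_reported_with_time_reached():
    # y' = y^2 from y(0)=1 blows up at t = 1
    def quad(u, v, t):
        return u * u, np.zeros_like(v)

    co = mp.etd_coefficients(np.array([0.0]), 0.05)
    s = mp.SpectralState(np.array([1.0 + 0j]), np.zeros(1, dtype=complex))
    with pytest.raises(BlowUpError) as exc:
        for _ in range(100):
            s = mp.etdrk4_step(s, co, co, quad)
    assert 0.5 <= exc.value.t_reached <= 1.5


# ---------------------------------------------------------------- integrate()

def test_homogeneous_prey_only_state_stays_constant(grid900, k_half):
    traj = mp.integrate(
        np.ones(grid900.N), np.zeros(grid900.N), grid900, k_half, dt=0.05, t_max=10.0
    )
    assert np.ptp(traj.mean_U) <= 1e-10 and np.max(np.abs(traj.mean_V)) <= 1e-10


def test_high_mortality_drives_predator_out(grid900):
    """For k2 above the coexistence threshold the prey recovers to carrying
    capacity while the predator dies out monotonically (late phase)."""
    k = mp.DimensionlessParams(1.0, 1.5)
    U0, V0 = mp.bump_initial_condition(grid900)
    traj = mp.integrate(U0, V0, grid900, k, dt=0.05, t_max=200.0, save_every=40)
    assert not traj.diverged
    assert traj.mean_U[-1] == pytest.approx(1.0, abs=1e-4)
    assert traj.mean_V[-1] <= 1e-4
    assert traj.mean_U[-1] > traj.mean_U[0]
    assert traj.mean_V[-1] < traj.mean_V[0]


def test_sawtooth_perturbation_is_damped(grid900, k_half):
    """The prey field has no diffusion, so its highest (Nyquist) mode is
    damped only through the nonlinear feedback; a sawtooth perturbation of
    the carrying-capacity state must decay, not grow."""
    N = grid900.N
    U0 = 1.0 + 1e-6 * (-1.0) ** np.arange(N)
    V0 = np.zeros(N)
    traj = mp.integrate(U0, V0, grid900, k_half, dt=0.05, t_max=10.0, save_every=20)
    dev = np.max(np.abs(traj.U - 1.0), axis=1)
    assert not traj.diverged
    assert dev[-1] < 1e-9  # linearized decay rate is -1


def test_integrate_is_deterministic(grid900, k_half):
    U0, V0 = mp.bump_initial_condition(grid900)
    a = mp.integrate(U0, V0, grid900, k_half, dt=0.05, t_max=5.0)
    b = mp.integrate(U0, V0, grid900, k_half, dt=0.05, t_max=5.0)
    assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)


def test_integrate_validates_inputs(grid900, k_half):
    with pytest.raises(InvalidParameterError):
        mp.integrate(np.ones(3), np.ones(3), grid900, k_half)
    with pytest.raises(InvalidParameterError):
        mp.integrate(
            np.ones(grid900.N), np.ones(grid900.N), grid900, k_half, dt=-0.1
        )


# ------------------------------------------------------------ integrate_ode()

def test_ode_zero_initial_state_stays_zero():
    p = mp.DimensionalParams(a1=1, a2=1, a3=1, a4=1, a5=0.5, a6=1)
    traj = mp.integrate_ode(0.0, 0.0, p, dt=0.01, t_max=5.0)
    assert np.max(np.abs(traj.U)) == 0.0 and np.max(np.abs(traj.V)) == 0.0


def test_ode_recovers_logistic_closed_form():
    p = mp.DimensionalParams(a1=1, a2=1)
    traj = mp.integrate_ode(0.5, 0.0, p, dt=0.002, t_max=10.0, save_every=50)
    exact = 1.0 / (1.0 + np.exp(-traj.t))
    assert np.max(np.abs(traj.mean_U - exact)) <= 1e-8


def test_ode_matches_adaptive_reference():
    p = mp.DimensionalParams(a1=1, a2=1, a3=1, a4=10, a5=0.5, a6=1)
    traj = mp.integrate_ode(1.0, 0.1, p, dt=0.001, t_max=5.0, save_every=5000)
    ref = solve_ivp(
        lambda t, y: mp.reaction_dimensional(y[0], y[1], p),
        [0, 5.0],
        [1.0, 0.1],
        rtol=1e-12,
        atol=1e-14,
    ).y[:, -1]
    assert traj.mean_U[-1] == pytest.approx(ref[0], abs=1e-9)
    assert traj.mean_V[-1] == pytest.approx(ref[1], abs=1e-9)


def test_strong_pair_predation_causes_overshoot_and_collapse():
    """With a4 = 10 the mating-pair term drives the predator population
    above the prey before the predators collapse for lack of food."""
    p = mp.DimensionalParams(a1=1, a2=1, a3=1, a4=10, a5=0.5, a6=1)
    traj = mp.integrate_ode(1.0, 0.1, p, dt=0.01, t_max=30.0)
    v, u = traj.mean_V, traj.mean_U
    ipeak = int(np.argmax(v))
    assert v[ipeak] > u[ipeak]
    assert v[-1] < v[ipeak]
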