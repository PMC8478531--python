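# Methods

## Model

The package simulates a prey–predator system in which predators hunt
both singly (`a3·u·v`) and as mating pairs (`a4·u·v²`).  Prey grow
logistically and do not move; predators diffuse, die at rate `a5`, and
compete among themselves (`a6·v²`).  All analysis and the PDE solver
work on the two-parameter dimensionless form

    U_t =        U − U² − U·V − U·V²
    V_t = V_XX − k1·k2·V − k1·V² + k1·U·V + k1·U·V²

with `k1 = a3/a2` (interaction strength) and `k2 = a5/(a1·k1)` (scaled
predator mortality).  The rescaling also admits an alternative reading
`k1 = √(a4·a1)/a2`, which ties `a4` to `a3`; `nondimensionalize` uses
`a3/a2` and emits a warning when the two expressions disagree, so that
inconsistent rate sets are visible rather than silently reinterpreted.

## Equilibria and stability

Setting both reaction terms to zero gives the extinction state (0, 0),
the prey-only state (1, 0), and interior states solving
`U = 1 − V − V²` and `U·(1 + V) = k2 + V`.  Eliminating `U` yields

    V³ + 2V² + V + (k2 − 1) = 0,

whose left side is strictly increasing for `V > 0`; hence exactly one
positive root exists iff `k2 < 1`, and the coexistence state exists in
that range only.  Roots are bracketed by sign change, polished by a
damped Newton iteration on the full 2-D system, and accepted only when
the reaction residual is at most 1e-10 — the residual check, not the
algebra, is the contract.

Stability comes from the eigenvalues of the reaction Jacobian; spatial
stability from the dispersion matrix `J − diag(0, q²)` (only `V`
diffuses).  Eigenvalues with `|Re λ| < 1e-9` are labelled *marginal* to
avoid over-interpreting numerically zero real parts.

Two structural facts follow from the Jacobian evaluated at the
coexistence state (using the equilibrium conditions to simplify):
`J₁₁ = −U*` and `J₂₂ = k1·V*·(U* − 1) < 0`, so the trace is strictly
negative for every `k1 > 0`, `0 < k2 < 1`, while the determinant is
positive.  The coexistence state is therefore a stable node or spiral
wherever it exists — there is no Hopf bifurcation — and since the
dispersion relation only lowers the trace and raises the determinant
with `q²`, no diffusion-driven (Turing) instability exists either:
only the predator diffuses, which is purely stabilizing here.  The
dynamical repertoire of the model is thus: decay to coexistence
(possibly through a slowly damped spiral transient that can look
oscillatory over a short window) for `k2 < 1`, and predator extinction
with prey recovery for `k2 > 1`.  The regime diagnostics report what
the trajectories actually do; they do not assume this analysis.

## Spatial discretization

Periodic domain `[0, L)`, `N` even collocation nodes, standard FFT
ordering; forward transform unnormalized, inverse carries `1/N`.  The
linear symbols are `c_U = 1` (prey: growth, no diffusion) and
`c_V = −q² − k1·k2`.  The diffusion sign is the dissipative one
demanded by `V_t = V_XX` (Fourier symbol of the second derivative is
`−q²`); an anti-dissipative sign would make every sub-grid mode grow
without bound.

Nonlinear terms are evaluated pseudospectrally.  The nonlinearity is
cubic, so the default dealiasing is zero padding to `4N` with the
Nyquist coefficient split across the ±N/2 slots: triple products of
retained modes reach wavenumber `3N/2 < 2N`, nothing wraps, and the
truncated result is the exact Galerkin projection (verified against an
O(N³) direct convolution-sum oracle at small N).  Two details matter
and are easy to get wrong:

- *The Nyquist mode must stay in the products.*  The prey equation has
  no diffusion; its linear factor `e^{Δt}` amplifies every mode
  equally, and the only damping of sawtooth content is the nonlinear
  feedback `−2U·δ` near `U = 1`.  Dropping the Nyquist mode from the
  products removes that feedback and roundoff grows as `e^t`.
- *Conjugate symmetry must be re-enforced each step* (a cheap spectral
  reflection), for the same reason: the imaginary-field component of
  roundoff is invisible to the real-valued nonlinear evaluation, so
  the prey symbol would amplify it unopposed.

After every inverse transform the imaginary residue is checked against
1e-8 relative to max(field scale, 1) and discarded; exceeding the bound
raises a numeric error, which the drivers convert into a `diverged`
trajectory flag.  The 2/3-rule ("twothirds") and no dealiasing
("none") are selectable for comparison.  Boundary conditions are
periodic by construction of the basis.

## Time integration

The four-stage Cox–Matthews ETDRK4 scheme integrates the diagonal
linear part exactly and treats the nonlinearity with fourth-order
quadrature.  Coefficients per mode, with `z = c·Δt`:

    E = e^z, E2 = e^{z/2}, Q = Δt·(e^{z/2} − 1)/z
    α = Δt·(−4 − z + e^z(4 − 3z + z²))/z³
    β = Δt·2·(2 + z + e^z(z − 2))/z³
    γ = Δt·(−4 − 3z − z² + e^z(4 − z))/z³

and the step is `y⁺ = E·y + α·N₀ + β·(Nₐ + N_b) + γ·N_c`.  The
fractions cancel catastrophically as `z → 0` (limits `Δt/2`, `Δt/6`,
`Δt/3`, `Δt/6`, confirmed by series expansion in the tests); below
`|z| = 1/2` they are evaluated as the mean of the entire function over
32 equispaced points on a unit circle around `z` (exact by the
mean-value property).  Threshold, point count and radius are exposed.

Stepping is fixed-step, coefficients precomputed once per run.
Defaults: `Δt = 0.05`, `t_max = 400`, samples every 20 steps, domain
`L = 900` with `N = 256` — values chosen so the benchmark initial data
are resolved and the slowest transients (decay rates ≈ 0.3) have long
since settled in the second half of the run.  Convergence diagnostics
use `T = 1` with `N = 64` (order study) and `N = 32` (adaptive-reference
comparison), sizes at which the reference computations are exact to
well below the measured errors and run in seconds.

ODE mode integrates the non-spatial dimensional system with the same
stepper, splitting `c_u = a1`, `c_v = −a5` so the linear growth/decay
is exact; any consistent splitting is fourth-order, this one handles
the stiffest linear term best.

## Regime diagnostics

Classification looks at the spatial mean of `V` (mode-0 dynamics
captures both regimes and is insensitive to where spatial features
sit) over the trailing half of the samples: peak-to-peak below 1e-5 is
steady; above 1e-3 with at least three successive inter-peak intervals
agreeing within 5% is periodic, with the period taken as the mean
spacing of parabolic-refined local maxima; diverged runs are flagged
as such and final means below 1e-6 as extinction.  The thresholds suit
signals of order 0.1–1 and are configurable.  Period estimation is
cross-checked against an autocorrelation oracle in the tests.

## Benchmark initial conditions

The bump fixture is `U0 = 6/35 − 2e-7·(x − 225)(x − 675)` and
`V0 = 116/245 − 3e-5·(x − 450) + 1.8e-4` on `L = 900` — a shallow
quadratic prey bump and a gentle predator ramp about the levels 0.171
and 0.474.  The printed source of these fields is corrupted, so the
family is fully parameterized; any alternative reading is reachable
through `InitialConditionSpec`.  Fields must evaluate strictly
positive or the spec is rejected.  `V0` has a small jump across the
periodic boundary; the associated Gibbs oscillation is ~0.002 and does
not threaten positivity at the default resolutions.

The non-spatial pair-predation scenario fixes `a1 = a2 = 1`,
`a5 = 0.5` and varies `a4`; the remaining values are the package's own
reconstruction, chosen once as `a3 = 1`, `a6 = 1`, `u0 = 1`,
`v0 = 0.1`: prey start at carrying capacity with a small predator
inoculum, and unit rates keep the comparison between the `u·v` and
`u·v²` channels symmetric.  With `a4 = 10` the predator peak (≈0.73)
exceeds the prey (≈0.15) before collapsing; with `a4 ≤ 1` the predator
never overtakes the prey.

## What the generators do not emulate

The fixtures are deterministic, smooth, 1-D fields; they contain no
demographic noise, no prey diffusion, no spatial heterogeneity in the
rates, and no 2-D geometry.  Passing tests therefore demonstrate the
correctness of the discretization, integrator and diagnostics on this
model class — not that the model describes any particular ecological
data set.

## Known limitations

- The equilibrium analysis above implies the dimensionless system has
  no limit cycle: low-mortality runs converge (through a damped
  spiral) to coexistence rather than sustaining oscillations.  The
  regime classifier's "periodic" label is exercised with synthetic
  signals; under the corrected dissipative diffusion sign no parameter
  setting of this model produces it from the PDE.
- Fixed step only; no adaptivity and no error control beyond the
  convergence harness.
- 1-D periodic domains only; the dispersion analysis covers a single
  spatial wavenumber at a time.
- `find_equilibria` reports homogeneous states; spatially patterned
  equilibria (none are expected, see the Turing argument above) are
  outside its scope.
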