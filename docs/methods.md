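# Methods

## The model

`fockpop` simulates the demography of a pre-agricultural metapopulation
on an `L x L` lattice of habitat cells with an operatorial (quantum-like)
technique.  Each cell α hosts two interacting quantities: the local human
population density `n_a(α)` and the local natural-resource density
`n_b(α)`, both confined to `[0, 1]` by construction.  Rather than
integrating a classical ODE for the densities, the state of the whole
lattice is a normalized vector Ψ in a fermionic Fock space: every cell
contributes two fermionic modes (humans, resources), the canonical
anticommutation relations (CAR) cap each mode's occupation at 1, and the
densities are expectation values of the number operators,

    n_α^(a)(t) = ⟨Ψ(t), a_α†a_α Ψ(t)⟩ = ‖a_α Ψ(t)‖²,

so densities automatically stay in `[0, 1]` for a unit-norm state.

The state evolves under a Schrödinger equation `i ∂Ψ/∂t = H(Ψ) Ψ` with a
self-adjoint, *state-dependent* Hamiltonian

    H = Σ_α H_α + H_M,
    H_α = ω_a(K_α) a_α†a_α + ω_b(K_α) b_α†b_α + λ(K_α)(a_α†b_α + b_α†a_α),
    H_M = Σ_{α≠β} p γ(K_α, K_β) a_α a_β†   (neighboring cells only),

driven everywhere by the per-cell resource/human ratio
`K_α = n_b(α)/n_a(α)`:

    ω_a = σ [exp(−(K − 1/τ)²) K]^{1/2}        (human inertia, grows with K)
    ω_b = σ [exp(−(K/τ)²) K⁻¹]^{1/2}          (resource inertia, falls with K)
    λ   = ω_a + ω_b + μ                        (predator-prey exchange)
    γ(K_α, K_β) = ω_b(K_α) + ω_b(K_β)          (migration drive)

The exchange term converts resources into humans and back, giving each
cell predator-prey cycles; the migration term moves human density toward
a neighboring cell and strengthens when either cell's resource/human
ratio is low — the mechanism coupling resource stress, migration, and
the population losses of ensuing competition/conflict.  Because every
term commutes with the total number operator, the global sum
`n^(a)(t) + n^(b)(t)` is a constant of motion: the carrying capacity is
`K = (n^(a)(0) + n^(b)(0))/2`, and humans can only grow at the expense
of resources and vice versa.

A note on the exponent grouping in `ω_a, ω_b`: the square root applies
to the whole bracket (Gaussian factor times `K^{±1}`).  This is the
reading consistent with the reference values frozen in the test suite
(e.g. `ω_a(1) ≈ 2.2284`, `ω_b(1) ≈ 0.21100` at the default parameters).

## Default parameters

| parameter | default | meaning (units: dimensionless) |
|-----------|---------|--------------------------------|
| σ (`sigma`) | 12.5 | overall strength of the density-ratio feedback |
| τ (`tau`)   | 0.35 | sensitivity scale of the ratio response |
| μ (`mu`)    | 0.25 | floor of the predator-prey exchange |
| p           | 1.0  | migration coupling between neighbors (0 = no migration) |
| K (`K_total`) | 0.5 | global carrying capacity (conserved mean density) |
| jitter      | 0.10 | relative spread of the initial per-cell densities |
| `eps_density` | 1e-10 | floor in the ratio `K_α` (keeps coefficients finite) |

These defaults are the published fit of the South-American
pre-agricultural phase (9–5 k years BP); they are the single source of
truth used by the config loader, the presets, and the acceptance runs.

Simulation time is dimensionless.  At the defaults the global density
completes a full oscillation roughly every 0.5–0.7 time units, so the
preset horizon of 30 time units contains several tens of periods; any
mapping to calendar kiloyears is a presentation-layer scale factor.

### Where the coefficients balance

A consequence of the chosen coefficient family worth knowing before
interpreting runs: the two inertia functions cross at `K* ≈ 0.77`
(`ω_a < ω_b` below, `ω_a > ω_b` above), not at `K = 1`.  In the
two-level block of a single cell the detuning `ω_a − ω_b` drives a net
transfer from resources to humans whenever `K_α > K*`, so a decoupled
cell initialized at `K_α ≈ 1` drifts until its human density sits about
13% above `K/L²` and oscillates there.  The global no-migration curve
therefore settles slightly *above* the nominal carrying capacity
(≈ `[1.01, 1.17]·K` across seeds at the defaults) rather than
fluctuating symmetrically about it; with migration switched on, the
large synchronized swings straddle `K` itself.  This is an intrinsic
property of the printed coefficient functions at `τ = 0.35` — the
balance point would sit at `K = 1` only for `τ = 2`.

## Mode ordering and the Jordan-Wigner convention

Ladder operators are realized with Jordan-Wigner parity strings, which
is what makes the full CAR hold for every mode pair (within and across
cells).  Modes are ordered cell by cell, `(a_0, b_0, a_1, b_1, …)`.
This ordering is a deliberate design choice with dynamical content: the
string of the intra-cell exchange `a_α†b_α` covers the modes strictly
between its two endpoints, so with cell-interleaved ordering the string
is empty and `H_α` acts on cell α alone.  Consequences:

* with `p = 0` the lattice decouples exactly into `L²` independent
  4-dimensional problems (`evolve_percell`), which is what makes
  1000-cell no-migration runs cheap and exactly equivalent to the full
  Fock-space evolution — an equivalence asserted to 1e-8 in the tests;
* a species-blocked ordering (all `a` modes, then all `b` modes) would
  thread the exchange string through other cells' modes, making `H_α`
  act beyond its own cell and breaking the decoupling (verified
  numerically: per-cell densities diverge by ~0.04 within a couple of
  oscillation periods on a 2×2 no-migration run).

The migration term `a_α a_β†` is evaluated with the strings exactly as
written; each unordered neighbor pair is stored once as the Hermitian
combination `a_α a_β† + a_β a_α†`, so the assembled `H` is exactly
Hermitian regardless of floating-point coefficient asymmetry.  The
default adjacency is the 4-neighborhood with open boundaries
(8-neighborhood and periodic wrapping are config options).

## Initialization

The run starts at the moment the carrying capacity has been reached:
per-cell human densities are drawn uniformly within ±`jitter` of
`K/L²`, rescaled multiplicatively (and redrawn if the rescaling leaves
the band) so the global human density equals `K` exactly, and resources
complement humans to `2K/L²` in every cell.  The state realizing these
densities is the per-cell product with real nonnegative amplitudes
`(√((1−n_a)(1−n_b)), √(n_a(1−n_b)), √((1−n_a)n_b), √(n_a n_b))` — the
minimal-structure (unentangled, phase-free) state consistent with the
prescribed densities.  All runs are deterministic given the seed.

## Integration

The nonlinearity (H depends on Ψ through the densities) rules out plain
matrix-exponential stepping, so the integrator is classical fixed-step
RK4 on the complex amplitude vector, with the coefficients reassembled
from the *stage* state at every RK stage (a frozen-per-step mode and a
fully frozen mode exist for diagnostics; the frozen one-cell limit has
the closed form `n_a(t) = cos²(λt)`, asserted to 1e-6).  The dt-halving
convergence test confirms 4th-order error decay.

Norm and the global `n_a + n_b` are monitored at every record point; a
norm drift beyond `norm_tol` aborts the run with a diagnostic (the
signal that `dt` is too large).  Ψ is never renormalized by default —
drift is evidence, not noise (an optional renormalize-every-N flag
exists, off by default).

Full-space runs apply H matrix-free: the diagonal (number-operator)
part is one BLAS product with the precomputed occupancy-bit matrix, and
the off-diagonal part is a fixed CSR skeleton (built once per run) whose
per-entry payload indexes a small signed-coefficient table rebuilt each
stage, executed by a numba kernel.  This path is asserted against the
independently assembled sparse Hamiltonian (explicit ladder-operator
products) on L ≤ 2.

## Problem sizes and numerical settings of the shipped runs

* Migration scenario (`paper-migration` preset): 3×3 lattice (state
  dimension 4⁹ = 262 144), horizon 30 with `dt = 5e-3` and densities
  recorded every 0.01 time units.  The horizon was chosen so the
  cumulative oscillation envelope saturates (it does by `t ≈ 20`); the
  step so that the interval statistics agree with a `dt = 2.5e-3` run
  to within the realization noise, with the norm drift (~1e-3 over the
  whole run, monitored against `norm_tol = 5e-3`) orders of magnitude
  below the amplitudes being measured.
* No-migration scenario (`paper-nomigration` preset): identical
  protocol with `p = 0` on the exact per-cell path at `dt = 1e-3` and
  `norm_tol = 1e-6`; lattices up to 1000 cells run in seconds.
* Property checks (CAR suite, Hermiticity, commutation, path
  equivalence) run exhaustively on L = 1 and L = 2 where the full
  operator algebra fits comfortably in memory.

The state-dependent flow is chaotic at the migration defaults:
perturbing `dt` or the seed re-samples the oscillatory attractor, and
min/max-over-window statistics carry an intrinsic wobble of roughly
±0.05 (in units of `K`) at horizon 30.  Statements about intervals are
therefore made per seed or over several seeds, never from a single
trajectory's last digit.

## What the synthetic reference emulates

`make_reference_fixture` produces a two-column demographic curve
oscillating about a carrying capacity `K_ref` (default 0.185, the scale
of the reconstructed South-American curve) with prescribed min/max
ratios (default 0.70 and 1.57), mild seeded harmonic distortion, and
exact attainment of the requested extremes at the sampled resolution.
It reproduces the *summary statistics* of a reconstructed demographic
curve — oscillation interval relative to K and major-extreme counts —
not its spectral content, time calibration, or sampling noise; a pass
against the fixture shows the comparison arithmetic is right, not that
the model fits any particular empirical dataset.

## Known limitations

* The mapping from simulation time to calendar years is not identified
  by the model; only dimensionless oscillation statistics are compared.
* Oscillation statistics of the migration scenario are seed-dependent at
  the ~0.05–0.1 level in `min/max` ratio; multi-seed protocols are used
  wherever a number is asserted.
* The model covers the capacity-equilibrium phase only: neither the
  colonization growth phase nor the agricultural expansion is modeled.
* Parameters are spatially uniform; per-cell heterogeneity beyond the
  initial jitter is not implemented.
* Lattices beyond L = 3 are impractical for the migration scenario (the
  state dimension grows as 4^(L²)); the no-migration fast path has no
  such limit.
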