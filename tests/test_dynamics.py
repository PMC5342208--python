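"""Evolution: densities, conservation, closed-form limits, convergence."""

import numpy as np
import pytest

from fockpop import (
    InitSpec,
    IntegrationError,
    LatticeSpec,
    ModelParams,
    basis_state,
    conservation_check,
    densities_from_state,
    evolve,
    evolve_percell,
    vacuum_state,
)
from fockpop.dynamics import CoefficientSet
from fockpop.scenarios import initial_cell_states, initial_state


class TestDensitiesFromState:
    def test_basis_state_density_is_occupation(self):
        lat = LatticeSpec(2)
        m_a, m_b = np.array([1, 0, 1, 0]), np.array([0, 0, 1, 1])
        f = densities_from_state(basis_state(lat, m_a, m_b), lat)
        assert np.array_equal(f.n_a, m_a)
        assert np.array_equal(f.n_b, m_b)

    def test_vacuum_all_zero(self):
        lat = LatticeSpec(2)
        f = densities_from_state(vacuum_state(lat), lat)
        assert not f.n_a.any() and not f.n_b.any()

    def test_superposition_half_half(self):
        # (phi_00 + phi_11)/sqrt(2) on one cell: n_a = n_b = 1/2
        lat = LatticeSpec(1)
        psi = (basis_state(lat, [0], [0]) + basis_state(lat, [1], [1])) / np.sqrt(2)
        f = densities_from_state(psi, lat)
        assert f.n_a[0] == pytest.approx(0.5, abs=1e-15)
        assert f.n_b[0] == pytest.approx(0.5, abs=1e-15)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            densities_from_state(np.ones(4), LatticeSpec(2))


class TestEvolve:
    def test_conservation_and_norm(self):
        """Global n_a + n_b and the state norm are flat to 1e-6 over a
        full nonlinear run."""
        lat = LatticeSpec(2)
        traj = evolve(
            initial_state(InitSpec(L=2, seed=3), lat),
            ModelParams(), lat, horizon=2.0, dt=1e-3, record_every=5,
        )
        report = conservation_check(traj, tol=1e-6)
        assert report["passed"], report
        total = traj.global_a + traj.global_b
        assert np.abs(total - total[0]).max() < 1e-6
        assert np.abs(traj.norm - 1).max() < 1e-6

    def test_densities_stay_in_unit_interval(self):
        lat = LatticeSpec(2)
        traj = evolve(
            initial_state(InitSpec(L=2, seed=5), lat),
            ModelParams(), lat, horizon=1.0, dt=1e-3,
        )
        for arr in (traj.n_a, traj.n_b):
            assert (arr >= 0).all() and (arr <= 1).all()

    def test_frozen_one_cell_rabi(self):
        """With coefficients frozen at omega_a = omega_b and the cell
        started at full human occupation, n_a(t) = cos^2(lambda t)."""
        lat = LatticeSpec(1)
        lam = 2.0
        coeffs = CoefficientSet(
            omega_a=np.array([1.3]), omega_b=np.array([1.3]),
            lam=np.array([lam]), gamma=np.zeros(0),
        )
        traj = evolve(
            basis_state(lat, [1], [0]), ModelParams(), lat,
            horizon=2.0, dt=1e-3, record_every=10,
            coefficient_update="frozen", frozen_coefficients=coeffs,
        )
        expected = np.cos(lam * traj.times) ** 2
        assert np.abs(traj.n_a[:, 0] - expected).max() < 1e-6

    def test_step_frozen_coefficients_mode(self):
        """Freezing coefficients over each step (instead of per stage)
        is a coarser but consistent scheme: same conserved quantities,
        trajectories agreeing to O(dt) on a short run."""
        lat = LatticeSpec(2)
        psi0 = initial_state(InitSpec(L=2, seed=21), lat)
        kw = dict(horizon=0.5, dt=1e-3, record_every=10)
        stage = evolve(psi0, ModelParams(), lat, coefficient_update="stage", **kw)
        step = evolve(psi0, ModelParams(), lat, coefficient_update="step", **kw)
        assert conservation_check(step, tol=1e-6)["passed"]
        assert np.abs(stage.n_a - step.n_a).max() < 5e-3
        with pytest.raises(ValueError, match="coefficient_update"):
            evolve(psi0, ModelParams(), lat, horizon=0.1, coefficient_update="never")

    def test_norm_drift_abort(self):
        # a grossly large step is unstable and must abort with a diagnostic
        lat = LatticeSpec(1)
        with pytest.raises(IntegrationError, match="reduce dt"):
            evolve(
                basis_state(lat, [1], [0]), ModelParams(), lat,
                horizon=50.0, dt=0.5, record_every=1,
            )

    def test_rejects_bad_inputs(self):
        lat = LatticeSpec(1)
        psi = basis_state(lat, [1], [0])
        with pytest.raises(ValueError):
            evolve(psi * 2, ModelParams(), lat, horizon=1.0)
        with pytest.raises(ValueError):
            evolve(psi, ModelParams(), lat, horizon=-1.0)
        with pytest.raises(ValueError):
            evolve(psi, ModelParams(), LatticeSpec(2), horizon=1.0)


class TestPerCellFastPath:
    def test_matches_full_evolution(self):
        """With migration off a product state stays a product; the 4-dim
        per-cell path must agree with the 256-dim evolution to 1e-8."""
        init = InitSpec(L=2, seed=11)
        lat = LatticeSpec(2)
        params = ModelParams(p=0.0)
        kw = dict(horizon=1.5, dt=1e-3, record_every=10)
        full = evolve(initial_state(init, lat), params, lat, **kw)
        fast = evolve_percell(initial_cell_states(init), params, **kw)
        assert np.abs(full.n_a - fast.n_a).max() < 1e-8
        assert np.abs(full.n_b - fast.n_b).max() < 1e-8
        assert np.allclose(full.times, fast.times)

    def test_rejects_migration(self):
        with pytest.raises(ValueError, match="p=0"):
            evolve_percell(
                initial_cell_states(InitSpec(L=2, seed=0)), ModelParams(p=1.0),
                horizon=1.0,
            )

    def test_per_cell_conservation(self):
        # each decoupled cell conserves its own n_a + n_b
        traj = evolve_percell(
            initial_cell_states(InitSpec(L=3, seed=2)), ModelParams(p=0.0),
            horizon=2.0, dt=1e-3,
        )
        total = traj.n_a + traj.n_b
        assert np.abs(total - total[0]).max() < 1e-9


class TestSinglePrecisionPath:
    def test_matches_double_precision(self):
        """complex64 stepping tracks the complex128 trajectory to well
        below the tolerances of any statistic computed from it."""
        lat = LatticeSpec(2)
        psi0 = initial_state(InitSpec(L=2, seed=13), lat)
        kw = dict(horizon=1.0, dt=1e-3, record_every=10, norm_tol=1e-4)
        t64 = evolve(psi0, ModelParams(), lat, dtype=np.complex64, **kw)
        t128 = evolve(psi0, ModelParams(), lat, dtype=np.complex128, **kw)
        assert np.abs(t64.n_a - t128.n_a).max() < 1e-4
        with pytest.raises(ValueError, match="dtype"):
            evolve(psi0, ModelParams(), lat, horizon=1.0, dtype=np.float64)


class TestConvergence:
    def test_rk4_order(self):
        """Halving dt shrinks the end-state density error by ~2^4."""
        lat = LatticeSpec(1)
        init = InitSpec(L=1, K_total=0.5, jitter=0.0, seed=0)
        params = ModelParams()
        psi0 = initial_state(init, lat)

        def final_density(dt):
            traj = evolve(psi0, params, lat, horizon=0.5, dt=dt,
                          record_every=10**9)
            return traj.n_a[-1, 0]

        ref = final_density(2.5e-4)
        errs = [abs(final_density(dt) - ref) for dt in (4e-3, 2e-3, 1e-3)]
        ratios = [errs[i] / errs[i + 1] for i in range(2)]
        for r in ratios:
            assert 10 < r < 26, (errs, ratios)


class TestConservationCheck:
    def test_flags_perturbed_trajectory(self):
        traj = evolve_percell(
            initial_cell_states(InitSpec(L=2, seed=1)), ModelParams(p=0.0),
            horizon=0.5, dt=1e-3,
        )
        assert conservation_check(traj, tol=1e-6)["passed"]
        traj.n_a[-1, 0] += 1e-3
        assert not conservation_check(traj, tol=1e-6)["passed"]

    def test_vacuum_identically_conserved(self):
        lat = LatticeSpec(1)
        traj = evolve(vacuum_state(lat), ModelParams(), lat, horizon=0.5, dt=1e-3)
        report = conservation_check(traj, tol=0.0)
        assert report["max_conservation_deviation"] == 0.0
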