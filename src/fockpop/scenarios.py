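"""Initialization protocol and the two study scenarios.

The initial state targets the moment the continent's carrying capacity
has just been reached: the global human density starts exactly at
``K_total`` (default 0.5), split across cells with a random jitter of at
most ±10% around ``K_total / L**2``, and per-cell resources complement
humans to ``2 K_total / L**2`` so that every cell starts at the shared
per-cell carrying capacity.  The state realizing these densities is the
unentangled per-cell product with real nonnegative amplitudes — the
minimal structure consistent with the prescribed densities.

Two scenarios are orchestrated on top of :mod:`fockpop.dynamics`:

* ``no_migration`` — migration coupling forced to 0; cells decouple
  exactly and the cheap per-cell path is used, enabling lattices of
  hundreds to thousands of cells.
* ``migration`` — the full Fock-space evolution with the
  migration-conflict coupling between neighboring cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import ModelParams
from .dynamics import Trajectory, evolve, evolve_percell
from .fock_space import LatticeSpec

__all__ = [
    "InitSpec",
    "draw_initial_densities",
    "initial_cell_states",
    "initial_state",
    "run_scenario",
    "parameter_sweep",
]

SCENARIOS = ("no_migration", "migration")


@dataclass(frozen=True)
class InitSpec:
    """Initialization protocol parameters."""

    L: int = 3
    K_total: float = 0.5
    jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0 < self.K_total <= 1:
            raise ValueError("K_total must be in (0, 1]")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter must be in [0, 1)")
        n_cells = self.L * self.L
        # both n_a(0) and n_b(0) = 2K/n - n_a(0) are bounded by (1+j) K / n
        if (1 + self.jitter) * self.K_total / n_cells > 1:
            raise ValueError(
                "infeasible initialization: per-cell densities would exceed 1"
            )


def draw_initial_densities(spec: InitSpec, max_tries: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell initial densities ``(n_a, n_b)``.

    ``n_a`` is drawn uniformly within ±jitter of ``K_total / n_cells``,
    rescaled multiplicatively so the global sum equals ``K_total``
    exactly, and redrawn if the rescaling pushes any cell outside the
    jitter band.  ``n_b = 2 K_total / n_cells - n_a`` per cell.
    Deterministic for a given seed.
    """
    n_cells = spec.L * spec.L
    target = spec.K_total / n_cells
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_tries):
        n_a = rng.uniform(target * (1 - spec.jitter), target * (1 + spec.jitter), n_cells)
        n_a *= spec.K_total / n_a.sum()
        # force the global sum to K_total to the last ulp
        n_a[-1] += spec.K_total - n_a.sum()
        if (n_a >= target * (1 - spec.jitter)).all() and (
            n_a <= target * (1 + spec.jitter)
        ).all():
            n_b = 2.0 * target - n_a
            return n_a, n_b
    raise RuntimeError("could not draw densities inside the jitter band")


def initial_cell_states(spec: InitSpec) -> np.ndarray:
    """Per-cell 4-component amplitudes realizing the drawn densities.

    Local basis order ``(m_a, m_b) = (0,0), (1,0), (0,1), (1,1)``;
    amplitudes are the real nonnegative square roots of the product
    Bernoulli weights, so cell densities come out exactly ``(n_a, n_b)``.
    """
    n_a, n_b = draw_initial_densities(spec)
    amps = np.empty((spec.L * spec.L, 4))
    amps[:, 0] = np.sqrt((1 - n_a) * (1 - n_b))
    amps[:, 1] = np.sqrt(n_a * (1 - n_b))
    amps[:, 2] = np.sqrt((1 - n_a) * n_b)
    amps[:, 3] = np.sqrt(n_a * n_b)
    return amps.astype(np.complex128)


def initial_state(spec: InitSpec, lattice: LatticeSpec) -> np.ndarray:
    """Full Fock-space product state over the occupation basis."""
    if lattice.L != spec.L:
        raise ValueError(f"lattice L={lattice.L} does not match init L={spec.L}")
    amps = initial_cell_states(spec)
    n = lattice.n_cells
    idx = np.arange(lattice.dim, dtype=np.int64)
    psi = np.ones(lattice.dim, dtype=np.complex128)
    for c in range(n):
        # cell c owns bits (2c, 2c+1) of the basis index: (m_a, m_b)
        psi *= amps[c, (idx >> (2 * c)) & 3]
    return psi


def run_scenario(
    name: str,
    params: ModelParams,
    lattice: LatticeSpec,
    init: InitSpec,
    horizon: float,
    dt: float = 1e-3,
    record_every: int = 10,
    **evolve_kwargs,
) -> Trajectory:
    """Run one of the two study scenarios and label the trajectory.

    ``no_migration`` forces ``p=0`` and takes the exact per-cell fast
    path (the initial state is always a product state here);
    ``migration`` runs the full Fock-space evolution.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    meta = evolve_kwargs.pop("meta", {})
    meta = {"scenario": name, "seed": init.seed, "K_total": init.K_total, **meta}
    if name == "no_migration":
        run_params = params.with_(p=0.0)
        traj = evolve_percell(
            initial_cell_states(init), run_params, horizon, dt, record_every,
            meta=meta, **evolve_kwargs,
        )
    else:
        if params.p == 0:
            raise ValueError("migration scenario requires p > 0")
        traj = evolve(
            initial_state(init, lattice), params, lattice, horizon, dt, record_every,
            meta=meta, **evolve_kwargs,
        )
    return traj


def parameter_sweep(
    params: ModelParams,
    lattice: LatticeSpec,
    init: InitSpec,
    axis: str,
    values,
    seeds,
    horizon: float,
    dt: float = 1e-3,
    record_every: int = 10,
    transient_frac: float = 0.05,
    **evolve_kwargs,
) -> tuple[list, pd.DataFrame]:
    """Sensitivity sweep along one parameter axis.

    For each ``(value, seed)`` the appropriate scenario is run (``p=0``
    uses the no-migration fast path) and its oscillation statistics are
    summarized.  Returns the trajectories and a tidy summary table.
    """
    from .analysis import count_extremes, oscillation_interval

    if axis not in ("p", "mu", "tau", "sigma"):
        raise ValueError(f"sweep axis must be one of p|mu|tau|sigma, got {axis!r}")
    runs, rows = [], []
    for value in values:
        swept = params.with_(**{axis: float(value)})
        for seed in seeds:
            ini = InitSpec(L=init.L, K_total=init.K_total, jitter=init.jitter, seed=int(seed))
            scenario = "no_migration" if swept.p == 0 else "migration"
            traj = run_scenario(
                scenario, swept, lattice, ini, horizon, dt, record_every,
                meta={"sweep_axis": axis, "sweep_value": float(value)},
                **evolve_kwargs,
            )
            summ = oscillation_interval(traj, transient_frac=transient_frac)
            peaks, valleys = count_extremes(traj, transient_frac=transient_frac)
            runs.append(traj)
            rows.append(
                {
                    "axis": axis, "value": float(value), "seed": int(seed),
                    "scenario": scenario,
                    "min_ratio": summ.min_ratio, "max_ratio": summ.max_ratio,
                    "std_ratio": summ.std_ratio,
                    "amplitude": summ.max_ratio - summ.min_ratio,
                    "n_major_peaks": peaks, "n_major_valleys": valleys,
                }
            )
    return runs, pd.DataFrame(rows)
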