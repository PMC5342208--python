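"""Assembly of the full lattice Hamiltonian ``H = sum_alpha H_alpha + H_M``.

Per cell (predator-prey part):

    H_alpha = omega_a(K_alpha) n_a(alpha) + omega_b(K_alpha) n_b(alpha)
              + lambda(K_alpha) (a_alpha^dag b_alpha + b_alpha^dag a_alpha)

Between neighboring cells (migration-conflict part):

    H_M = sum_{alpha != beta} p * gamma(K_alpha, K_beta) * a_alpha a_beta^dag

The operator structure never changes during a run; only the coefficients
do. ``HamiltonianTerms`` therefore caches the Hermitian building blocks
once (each unordered neighbor pair stored as the Hermitian combination
``a_alpha a_beta^dag + a_beta a_alpha^dag``, with the fermionic strings
evaluated exactly as written) and :func:`assemble_hamiltonian` only
rescales them, which keeps every assembled ``H`` exactly Hermitian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .coefficients import DensityField, ModelParams, gamma_coeff, lambda_coeff, omega_a, omega_b
from .fock_space import LatticeSpec, ladder_operator, number_operator

__all__ = ["neighbor_pairs", "HamiltonianTerms", "assemble_hamiltonian"]


def neighbor_pairs(
    lattice: LatticeSpec, connectivity: int = 4, periodic: bool = False
) -> list[tuple[int, int]]:
    """Unordered neighbor cell pairs ``(alpha, beta)`` with ``alpha < beta``.

    The default is the 4-neighborhood (von Neumann) with open boundaries;
    ``connectivity=8`` adds diagonals and ``periodic=True`` wraps the
    lattice into a torus.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    L = lattice.L
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    pairs: set[tuple[int, int]] = set()
    for r in range(L):
        for c in range(L):
            for dr, dc in offsets:
                r2, c2 = r + dr, c + dc
                if periodic:
                    r2, c2 = r2 % L, c2 % L
                elif not (0 <= r2 < L and 0 <= c2 < L):
                    continue
                a, b = lattice.cell_index(r, c), lattice.cell_index(r2, c2)
                if a != b:
                    pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


@dataclass(frozen=True)
class HamiltonianTerms:
    """Cached Hermitian operator blocks of the Hamiltonian.

    Attributes
    ----------
    lattice : LatticeSpec
    pairs : list of (int, int)
        Neighbor pairs carrying a migration term.
    n_a, n_b : list of sparse matrices
        Diagonal number operators per cell.
    exchange : list of sparse matrices
        ``a^dag b + b^dag a`` per cell.
    migration : list of sparse matrices
        ``a_alpha a_beta^dag + a_beta a_alpha^dag`` per neighbor pair.
    """

    lattice: LatticeSpec
    pairs: list
    n_a: list
    n_b: list
    exchange: list
    migration: list

    @classmethod
    def build(
        cls,
        lattice: LatticeSpec,
        connectivity: int = 4,
        periodic: bool = False,
    ) -> "HamiltonianTerms":
        pairs = neighbor_pairs(lattice, connectivity, periodic)
        ann_a = [ladder_operator(lattice, "a", c) for c in range(lattice.n_cells)]
        ann_b = [ladder_operator(lattice, "b", c) for c in range(lattice.n_cells)]
        n_a = [number_operator(lattice, "a", c) for c in range(lattice.n_cells)]
        n_b = [number_operator(lattice, "b", c) for c in range(lattice.n_cells)]
        exchange = []
        for c in range(lattice.n_cells):
            x = ann_a[c].getH() @ ann_b[c]
            exchange.append((x + x.getH()).tocsr())
        migration = []
        for a, b in pairs:
            m = ann_a[a] @ ann_a[b].getH()
            migration.append((m + m.getH()).tocsr())
        return cls(lattice, pairs, n_a, n_b, exchange, migration)


def assemble_hamiltonian(
    terms: HamiltonianTerms, densities: DensityField, params: ModelParams
) -> sp.csr_matrix:
    """Hamiltonian for the instantaneous density field.

    Coefficients are evaluated from the per-cell ratio ``K_alpha`` and
    contracted against the cached blocks; the result is exactly Hermitian
    because the coefficients are real and every block is Hermitian.
    """
    lattice = terms.lattice
    if densities.n_a.shape != (lattice.n_cells,):
        raise ValueError(
            f"density field has {densities.n_a.shape[0]} cells, lattice has {lattice.n_cells}"
        )
    K = densities.K_ratio(params.eps_density)
    wa = omega_a(K, params)
    wb = omega_b(K, params)
    lam = lambda_coeff(K, params)
    H = sp.csr_matrix((lattice.dim, lattice.dim), dtype=np.complex128)
    for c in range(lattice.n_cells):
        H = H + wa[c] * terms.n_a[c] + wb[c] * terms.n_b[c] + lam[c] * terms.exchange[c]
    for (a, b), M in zip(terms.pairs, terms.migration):
        H = H + (params.p * gamma_coeff(K[a], K[b], params)) * M
    return H.tocsr()
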