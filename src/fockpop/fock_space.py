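"""Fermionic Fock space for a two-species square lattice.

Each of the ``L**2`` cells of an ``L x L`` lattice carries two fermionic
modes: species ``"a"`` (humans) and species ``"b"`` (natural resources).
The occupation of a mode is 0 or 1, so a single cell spans a 4-dimensional
local space with basis states ``(m_a, m_b) in {0,1}^2`` and the full
lattice Hilbert space has dimension ``4**(L**2)``.

Ladder operators are built with a Jordan-Wigner string so that the
canonical anticommutation relations (CAR) hold exactly:

    {a_alpha, a_beta^dag} = {b_alpha, b_beta^dag} = delta_{alpha beta} * I
    a^2 = b^2 = 0,   all cross-species / cross-cell anticommutators vanish.

Mode ordering convention: modes are grouped by cell and interleaved as
``(a_0, b_0, a_1, b_1, ...)``; mode ``k`` is bit ``k`` of the basis-state
index, with ``a_0`` the least-significant bit, so each cell owns a
contiguous 2-bit group of the index.  Cells are indexed 0-based in
row-major order.  This ordering keeps the Jordan-Wigner string of the
intra-cell exchange ``a^dag b`` empty, so the per-cell Hamiltonian is
exactly cell-local and the no-migration dynamics decouples exactly —
while the CAR still holds globally for every mode pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LatticeSpec",
    "encode_occupation",
    "decode_occupation",
    "ladder_operator",
    "number_operator",
    "vacuum_state",
    "basis_state",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the ``L x L`` cell lattice.

    Parameters
    ----------
    L : int
        Side length; the lattice has ``L**2`` cells and ``2 * L**2``
        fermionic modes.
    """

    L: int

    def __post_init__(self) -> None:
        if not isinstance(self.L, (int, np.integer)) or self.L < 1:
            raise ValueError(f"L must be a positive integer, got {self.L!r}")

    @property
    def n_cells(self) -> int:
        return self.L * self.L

    @property
    def n_modes(self) -> int:
        return 2 * self.n_cells

    @property
    def dim(self) -> int:
        """Dimension of the Fock space, ``4**(L**2)``."""
        return 1 << self.n_modes

    def cell_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.L and 0 <= col < self.L):
            raise ValueError(f"(row, col)=({row}, {col}) outside {self.L}x{self.L} lattice")
        return row * self.L + col

    def row_col(self, cell: int) -> tuple[int, int]:
        self._check_cell(cell)
        return divmod(cell, self.L)

    def mode_index(self, species: str, cell: int) -> int:
        """Linear mode index of ``(species, cell)`` in the Jordan-Wigner order."""
        self._check_cell(cell)
        if species == "a":
            return 2 * cell
        if species == "b":
            return 2 * cell + 1
        raise ValueError(f"species must be 'a' or 'b', got {species!r}")

    def _check_cell(self, cell: int) -> None:
        if not (0 <= cell < self.n_cells):
            raise ValueError(f"cell index {cell} outside [0, {self.n_cells})")


def _as_bits(v, n_cells: int, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.shape != (n_cells,):
        raise ValueError(f"{name} must have length {n_cells}, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} entries must be 0 or 1")
    return arr.astype(np.int64)


def encode_occupation(m_a, m_b) -> int:
    """Linear basis index of the occupation pair ``(m_a, m_b)``.

    The index is the occupation bitstring read as an integer in the
    cell-interleaved mode order: ``m_a[0]`` is the least-significant
    bit, ``m_b[0]`` the next, then cell 1, and so on;
    ``decode_occupation`` inverts it.
    """
    m_a = np.asarray(m_a)
    m_b = np.asarray(m_b)
    if m_a.shape != m_b.shape or m_a.ndim != 1:
        raise ValueError("m_a and m_b must be 1-D with equal length")
    n = m_a.shape[0]
    m_a = _as_bits(m_a, n, "m_a")
    m_b = _as_bits(m_b, n, "m_b")
    weights = 1 << (2 * np.arange(n, dtype=np.int64))
    return int(m_a @ weights + 2 * (m_b @ weights))


def decode_occupation(index: int, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode_occupation`."""
    dim = 1 << (2 * n_cells)
    if not (0 <= index < dim):
        raise ValueError(f"index {index} outside [0, {dim})")
    bits = (index >> np.arange(2 * n_cells, dtype=np.int64)) & 1
    return bits[0::2].copy(), bits[1::2].copy()


def _mode_bits(lattice: LatticeSpec, mode: int) -> np.ndarray:
    idx = np.arange(lattice.dim, dtype=np.int64)
    return (idx >> mode) & 1


def ladder_operator(
    lattice: LatticeSpec, species: str, cell: int, dagger: bool = False
) -> sp.csr_matrix:
    """Sparse annihilation (or creation) operator for one mode.

    The operator carries the Jordan-Wigner parity string over all modes
    below it, which is what enforces the CAR across cells and species.
    The returned matrix has exactly ``dim/2`` nonzeros, all +-1.
    """
    mode = lattice.mode_index(species, cell)
    dim = lattice.dim
    idx = np.arange(dim, dtype=np.int64)
    occupied = ((idx >> mode) & 1) == 1
    src = idx[occupied]                      # states with the mode occupied
    dst = src ^ (1 << mode)                  # same states with it emptied
    lower = src & ((1 << mode) - 1)
    sign = 1.0 - 2.0 * (np.bitwise_count(lower.astype(np.uint64)).astype(np.float64) % 2)
    data = sign.astype(np.complex128)
    if dagger:
        mat = sp.coo_matrix((data, (src, dst)), shape=(dim, dim))
    else:
        mat = sp.coo_matrix((data, (dst, src)), shape=(dim, dim))
    return mat.tocsr()


def number_operator(lattice: LatticeSpec, species: str, cell: int) -> sp.csr_matrix:
    """Diagonal number operator ``n = c^dag c`` of one mode.

    Its eigenvalue on a basis state is that state's occupation bit, which
    is what lets densities be read off as expectation values.
    """
    mode = lattice.mode_index(species, cell)
    return sp.diags(_mode_bits(lattice, mode).astype(np.complex128), format="csr")


def vacuum_state(lattice: LatticeSpec) -> np.ndarray:
    """Unit vector on the all-empty occupation (near-absence of both
    humans and resources in every cell)."""
    psi = np.zeros(lattice.dim, dtype=np.complex128)
    psi[0] = 1.0
    return psi


def basis_state(lattice: LatticeSpec, m_a, m_b) -> np.ndarray:
    """Unit vector on the occupation pair ``(m_a, m_b)``."""
    psi = np.zeros(lattice.dim, dtype=np.complex128)
    psi[encode_occupation(m_a, m_b)] = 1.0
    return psi
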