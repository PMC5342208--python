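"""Numba kernels for the hot inner loops of the full-space evolution.

The off-diagonal part of the Hamiltonian has a fixed sparsity structure;
only the per-term coefficients change along a run.  The kernels consume
a precomputed CSR skeleton whose per-entry payload indexes a small
signed-coefficient table rebuilt at every RK stage.

The diagonal (number-operator) contribution and the per-cell occupation
probabilities exploit the cell-interleaved bit layout of the basis
index: cells are packed three to a "group" of 6 bits, so both reduce to
one 64-entry table lookup per group per basis state (the group tables
are rebuilt from the per-cell coefficient tables each stage, and the
group probability histograms are unfolded to per-cell densities
outside the kernel).

A full RK4 step is four fused stage calls: each applies ``H`` to the
stage vector, writes the next stage vector and the Runge-Kutta
accumulator in the same pass, and histograms the next stage vector's
occupation probabilities (the densities that drive the next stage's
coefficients).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "GROUP_BITS",
    "GROUP_STATES",
    "apply_h_csr",
    "group_probabilities",
    "rk4_stage",
    "rk4_final",
]

GROUP_BITS = 6          # cells per group * 2 bits per cell
GROUP_STATES = 1 << GROUP_BITS


@njit(cache=True, boundscheck=False)
def apply_h_csr(indptr, indices, eterm, signed_coeffs, wtab, psi, out):
    """``out = H @ psi`` (reference-path version, per-cell diagonal table).

    ``eterm[e]`` indexes ``signed_coeffs`` (two slots per off-diagonal
    term: +coefficient and -coefficient, the sign being the fermionic
    string parity of the entry).  ``wtab[c, s]`` is the diagonal weight
    of cell ``c`` in local occupation state ``s``.
    """
    n = psi.shape[0]
    n_cells = wtab.shape[0]
    for i in range(n):
        d = 0.0
        s = i
        for c in range(n_cells):
            d += wtab[c, s & 3]
            s >>= 2
        acc = d * psi[i]
        for e in range(indptr[i], indptr[i + 1]):
            acc += signed_coeffs[eterm[e]] * psi[indices[e]]
        out[i] = acc


@njit(cache=True, boundscheck=False)
def group_probabilities(psi, pg):
    """Histogram ``|psi_i|^2`` over each group's 6-bit local state."""
    pg[:] = 0.0
    ng = pg.shape[0]
    for i in range(psi.shape[0]):
        p = psi[i].real * psi[i].real + psi[i].imag * psi[i].imag
        s = i
        for g in range(ng):
            pg[g, s & 63] += p
            s >>= 6


@njit(cache=True, boundscheck=False)
def rk4_stage(indptr, indices, eterm, signed_coeffs, wg,
              x, psi_base, cs, ca, y_next, acc, pg):
    """One inner RK4 stage.

    ``h = H @ x``; ``y_next = psi_base - cs*i*h``; ``acc -= ca*i*h``;
    ``pg`` histograms the occupation probabilities of ``y_next`` for
    the next stage's coefficients.  ``wg[g, s]`` is the diagonal weight
    of group ``g`` in 6-bit local state ``s``.
    """
    n = x.shape[0]
    ng = wg.shape[0]
    pg[:] = 0.0
    for i in range(n):
        d = wg[0, i & 63]
        s = i >> 6
        for g in range(1, ng):
            d += wg[g, s & 63]
            s >>= 6
        h = d * x[i]
        for e in range(indptr[i], indptr[i + 1]):
            h += signed_coeffs[eterm[e]] * x[indices[e]]
        yr = psi_base[i].real + cs * h.imag
        yi = psi_base[i].imag - cs * h.real
        y_next[i] = complex(yr, yi)
        acc[i] = complex(acc[i].real + ca * h.imag, acc[i].imag - ca * h.real)
        p = yr * yr + yi * yi
        pg[0, i & 63] += p
        s = i >> 6
        for g in range(1, ng):
            pg[g, s & 63] += p
            s >>= 6


@njit(cache=True, boundscheck=False)
def rk4_final(indptr, indices, eterm, signed_coeffs, wg, x, ca, acc, pg):
    """Last RK4 stage: fold ``-ca*i*H@x`` into the accumulator (the new
    state) and histogram its occupation probabilities."""
    n = x.shape[0]
    ng = wg.shape[0]
    pg[:] = 0.0
    for i in range(n):
        d = wg[0, i & 63]
        s = i >> 6
        for g in range(1, ng):
            d += wg[g, s & 63]
            s >>= 6
        h = d * x[i]
        for e in range(indptr[i], indptr[i + 1]):
            h += signed_coeffs[eterm[e]] * x[indices[e]]
        yr = acc[i].real + ca * h.imag
        yi = acc[i].imag - ca * h.real
        acc[i] = complex(yr, yi)
        p = yr * yr + yi * yi
        pg[0, i & 63] += p
        s = i >> 6
        for g in range(1, ng):
            pg[g, s & 63] += p
            s >>= 6
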