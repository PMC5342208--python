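"""Fock-space construction: basis encoding, CAR algebra, number operators."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fockpop import (
    LatticeSpec,
    basis_state,
    decode_occupation,
    encode_occupation,
    ladder_operator,
    number_operator,
    vacuum_state,
)


def dense(op):
    return np.asarray(op.todense())


class TestLatticeSpec:
    def test_cell_indexing_bijective(self):
        lat = LatticeSpec(3)
        seen = set()
        for r in range(3):
            for c in range(3):
                i = lat.cell_index(r, c)
                assert lat.row_col(i) == (r, c)
                seen.add(i)
        assert seen == set(range(9))

    def test_dimension(self):
        assert LatticeSpec(1).dim == 4
        assert LatticeSpec(3).dim == 4**9 == 262144

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_side_length(self, bad):
        with pytest.raises(ValueError):
            LatticeSpec(bad)


class TestEncoding:
    def test_single_cell_has_four_states(self):
        lat = LatticeSpec(1)
        indices = {
            encode_occupation([ma], [mb]) for ma in (0, 1) for mb in (0, 1)
        }
        assert indices == {0, 1, 2, 3}
        assert lat.dim == 4

    @given(st.integers(1, 3), st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_round_trip(self, L, data):
        n = L * L
        m_a = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        m_b = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        idx = encode_occupation(m_a, m_b)
        assert 0 <= idx < 4**n
        ra, rb = decode_occupation(idx, n)
        assert list(ra) == m_a and list(rb) == m_b

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            encode_occupation([0, 1], [1])
        with pytest.raises(ValueError):
            encode_occupation([0, 2], [1, 0])
        with pytest.raises(ValueError):
            decode_occupation(16, 1)


def all_ladders(lat):
    """All annihilation operators keyed by (species, cell)."""
    return {
        (s, c): ladder_operator(lat, s, c)
        for s in "ab"
        for c in range(lat.n_cells)
    }


@pytest.mark.parametrize("L", [1, 2])
class TestCAR:
    """Canonical anticommutation relations, exhaustively on L=1 and L=2."""

    def test_car_suite(self, L):
        lat = LatticeSpec(L)
        ops = all_ladders(lat)
        eye = np.eye(lat.dim)
        keys = list(ops)
        for k1, k2 in itertools.product(keys, keys):
            x, y = ops[k1], ops[k2]
            anti_xy_dag = dense(x @ y.getH() + y.getH() @ x)
            expected = eye if k1 == k2 else 0.0
            assert np.abs(anti_xy_dag - expected).max() < 1e-14, (k1, k2)
            anti_xy = dense(x @ y + y @ x)
            assert np.abs(anti_xy).max() < 1e-14, (k1, k2)

    def test_nilpotent(self, L):
        lat = LatticeSpec(L)
        for op in all_ladders(lat).values():
            assert (op @ op).nnz == 0

    def test_dagger_is_adjoint(self, L):
        lat = LatticeSpec(L)
        for s in "ab":
            for c in range(lat.n_cells):
                a = ladder_operator(lat, s, c)
                adag = ladder_operator(lat, s, c, dagger=True)
                assert np.abs(dense(adag - a.getH())).max() == 0

    def test_ladder_sparsity(self, L):
        lat = LatticeSpec(L)
        for op in all_ladders(lat).values():
            assert op.nnz == lat.dim // 2


class TestNumberOperator:
    def test_eigenvalue_is_occupation_bit(self):
        lat = LatticeSpec(2)
        rng = np.random.default_rng(7)
        for _ in range(5):
            m_a = rng.integers(0, 2, 4)
            m_b = rng.integers(0, 2, 4)
            phi = basis_state(lat, m_a, m_b)
            for c in range(4):
                na = number_operator(lat, "a", c) @ phi
                assert np.allclose(na, m_a[c] * phi, atol=1e-15)
                nb = number_operator(lat, "b", c) @ phi
                assert np.allclose(nb, m_b[c] * phi, atol=1e-15)

    def test_annihilates_vacuum(self):
        lat = LatticeSpec(2)
        vac = vacuum_state(lat)
        assert np.abs(number_operator(lat, "a", 0) @ vac).max() == 0

    def test_trace_counts_half_the_basis(self):
        # half of all occupation bitstrings occupy any given mode
        lat = LatticeSpec(2)
        for s, c in (("a", 0), ("b", 3)):
            tr = number_operator(lat, s, c).diagonal().sum()
            assert tr == lat.dim / 2

    def test_rejects_invalid_cell(self):
        lat = LatticeSpec(2)
        with pytest.raises(ValueError):
            number_operator(lat, "a", 4)
        with pytest.raises(ValueError):
            ladder_operator(lat, "b", -1)
        with pytest.raises(ValueError):
            ladder_operator(lat, "c", 0)


class TestVacuumAndBasis:
    def test_vacuum_annihilated_by_all(self):
        lat = LatticeSpec(2)
        vac = vacuum_state(lat)
        assert np.linalg.norm(vac) == 1.0
        for op in all_ladders(lat).values():
            assert np.abs(op @ vac).max() == 0

    def test_single_cell_basis_construction(self):
        """The L=1 basis matches the explicit four-vector construction:
        phi_10 = a† phi_00, phi_01 = b† phi_00, phi_11 = a† b† phi_00."""
        lat = LatticeSpec(1)
        vac = vacuum_state(lat)
        adag = ladder_operator(lat, "a", 0, dagger=True)
        bdag = ladder_operator(lat, "b", 0, dagger=True)
        constructed = {
            (0, 0): vac,
            (1, 0): adag @ vac,
            (0, 1): bdag @ vac,
            (1, 1): adag @ (bdag @ vac),
        }
        for (ma, mb), vec in constructed.items():
            assert np.allclose(vec, basis_state(lat, [ma], [mb]), atol=1e-15)
        # mutual orthonormality
        mat = np.column_stack(list(constructed.values()))
        assert np.allclose(mat.conj().T @ mat, np.eye(4), atol=1e-15)
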