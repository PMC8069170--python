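"""Norm-index descriptor machinery against independent oracles.

Oracles: breadth-first search for the step matrix, explicit loops for the
three matrix norms, eigendecomposition of EM^T EM for the spectral norm.
"""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normsar import (
    DESCRIPTOR_NAMES,
    Molecule,
    assign_charges,
    descriptor_vector,
    euclidean_matrix,
    norm_index,
    property_matrix,
    step_matrix,
)
from normsar.descriptors import extended_matrix

from conftest import chain_molecule


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bfs_step_oracle(n, bonds):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(bonds)
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        lengths = nx.single_source_shortest_path_length(g, i)
        for j, L in lengths.items():
            d[i, j] = L
    return d


def norm1_oracle(em):
    best = 0.0
    for j in range(em.shape[1]):
        s = sum(abs(em[i, j]) for i in range(em.shape[0]))
        best = max(best, s)
    return best


def norm2_oracle(em):
    eigvals = np.linalg.eigvalsh(em.T @ em)
    return float(np.sqrt(max(eigvals.max(), 0.0)))


def norm3_oracle(em):
    total = 0.0
    for i in range(em.shape[0]):
        for j in range(em.shape[1]):
            total += em[i, j] ** 2
    return float(np.sqrt(total))


# ---------------------------------------------------------------------------
# step and Euclidean matrices
# ---------------------------------------------------------------------------

class TestStepMatrix:
    def test_linear_chain(self):
        m = chain_molecule(["C", "C", "C"])
        d = step_matrix(m)
        assert d[0, 2] == 2 and d[0, 1] == 1 and np.all(np.diag(d) == 0)

    def test_single_atom(self):
        m = Molecule(id="a", elements=["C"], bonds=set(), coords=np.zeros((1, 3)))
        assert step_matrix(m).tolist() == [[0]]

    def test_cyclohexane_skeleton_max_three(self):
        bonds = {(i, (i + 1) % 6) for i in range(6)}
        coords = np.array(
            [[np.cos(t), np.sin(t), 0.0] for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        )
        m = Molecule(id="c6", elements=["C"] * 6, bonds=bonds, coords=coords)
        d = step_matrix(m)
        np.testing.assert_array_equal(d, bfs_step_oracle(6, bonds))
        assert d.max() == 3

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=12), st.randoms(use_true_random=False))
    def test_matches_bfs_oracle_on_random_connected_graphs(self, n, rnd):
        g = nx.gnp_random_graph(n, 0.4, seed=rnd.randrange(10**6))
        # force connectivity with a spanning path
        g.add_edges_from((i, i + 1) for i in range(n - 1))
        bonds = set(g.edges())
        m = Molecule(id="g", elements=["C"] * n, bonds=bonds, coords=np.zeros((n, 3)))
        np.testing.assert_array_equal(step_matrix(m), bfs_step_oracle(n, bonds))

    def test_disconnected_raises(self):
        m = Molecule(id="x", elements=["C", "C", "C"], bonds={(0, 1)}, coords=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="disconnected"):
            step_matrix(m)


class TestEuclideanMatrix:
    def test_two_atoms(self):
        m = Molecule(
            id="d", elements=["C", "C"], bonds={(0, 1)},
            coords=np.array([[0.0, 0, 0], [0, 0, 1.5]]),
        )
        np.testing.assert_allclose(euclidean_matrix(m), [[0, 1.5], [1.5, 0]])

    def test_equilateral(self):
        d = 1.4
        coords = d * np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        m = Molecule(id="t", elements=["C"] * 3, bonds={(0, 1), (1, 2)}, coords=coords)
        e = euclidean_matrix(m)
        off = e[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, d)

    def test_rotation_invariance(self, small_molecules):
        from scipy.spatial.transform import Rotation

        m = small_molecules[0]
        R = Rotation.from_euler("zyx", [0.3, -1.2, 2.0]).as_matrix()
        rotated = Molecule(
            id=m.id, elements=m.elements, bonds=m.bonds,
            coords=m.coords @ R.T + np.array([1.0, -2.0, 3.0]),
            charges=m.charges, formal_charge=m.formal_charge,
        )
        np.testing.assert_allclose(euclidean_matrix(rotated), euclidean_matrix(m), atol=1e-9)

    def test_triangle_inequality(self, small_molecules):
        e = euclidean_matrix(small_molecules[1])
        n = e.shape[0]
        for i in range(n):
            for j in range(n):
                assert e[i, j] <= e[i].max() + e[j].max() + 1e-9
                for k in range(min(n, 6)):
                    assert e[i, j] <= e[i, k] + e[k, j] + 1e-9


# ---------------------------------------------------------------------------
# property and extended matrices
# ---------------------------------------------------------------------------

class TestPropertyMatrix:
    def test_hydrogen_row(self):
        m = chain_molecule(["H", "H"], bond_length=0.74)
        pm = property_matrix(m)
        np.testing.assert_allclose(pm[0], [1, 2.20, 13.598, 0.0], atol=1e-12)

    def test_tanh_saturates_below_one(self, water):
        m = Molecule(
            id="art", elements=water.elements, bonds=water.bonds, coords=water.coords,
            charges=np.array([10.0, -5.0, -5.0]), formal_charge=0,
        )
        pm = property_matrix(m)
        assert 0.99 < pm[0, 3] < 1.0

    def test_column_ranges(self, small_molecules):
        for m in small_molecules:
            pm = property_matrix(m)
            assert (pm[:, :3] > 0).all()
            assert (np.abs(pm[:, 3]) < 1).all()


class TestExtendedMatrix:
    def test_em2_zero_column_is_dm(self):
        dm = np.array([[0.0, 1], [1, 0]])
        np.testing.assert_array_equal(extended_matrix("EM2", dm, np.zeros(2)), dm)

    def test_em3_unit_column_is_dm(self):
        dm = np.array([[0.0, 2], [2, 0]])
        np.testing.assert_array_equal(extended_matrix("EM3", dm, np.ones(2)), dm)

    def test_em1_shape(self):
        dm = np.zeros((5, 5))
        assert extended_matrix("EM1", dm, np.ones(5)).shape == (5, 6)

    def test_em2_em3_symmetry_and_zero_diagonal(self, small_molecules):
        m = small_molecules[2]
        dm = euclidean_matrix(m)
        p = property_matrix(m)[:, 1]
        em2 = extended_matrix("EM2", dm, p)
        em3 = extended_matrix("EM3", dm, p)
        np.testing.assert_allclose(em2, em2.T)
        np.testing.assert_allclose(em3, em3.T)
        np.testing.assert_allclose(np.diag(em3), 0.0)

    def test_em3_matmul_option_differs(self):
        dm = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        p = np.array([1.0, 2.0, 3.0])
        h = extended_matrix("EM3", dm, p, em3_product="hadamard")
        mm = extended_matrix("EM3", dm, p, em3_product="matmul")
        assert not np.allclose(h, mm)
        np.testing.assert_allclose(mm, np.outer(p, p) @ dm)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            extended_matrix("EM2", np.zeros((3, 3)), np.ones(4))


# ---------------------------------------------------------------------------
# norm indexes
# ---------------------------------------------------------------------------

matrices = st.integers(min_value=1, max_value=20).flatmap(
    lambda n: st.integers(min_value=1, max_value=20).flatmap(
        lambda m: st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=n * m, max_size=n * m,
        ).map(lambda vals: np.array(vals).reshape(n, m))
    )
)


class TestNormIndex:
    def test_identity(self):
        eye = np.eye(3)
        assert norm_index(eye, 1) == pytest.approx(1)
        assert norm_index(eye, 2) == pytest.approx(1)
        assert norm_index(eye, 3) == pytest.approx(np.sqrt(3))

    def test_hand_example(self):
        em = np.array([[3.0, 0], [4, 0]])
        assert norm_index(em, 1) == pytest.approx(7)
        assert norm_index(em, 2) == pytest.approx(5)  # singular values (5, 0)
        assert norm_index(em, 3) == pytest.approx(5)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(matrices)
    def test_matches_oracles(self, em):
        assert norm_index(em, 1) == pytest.approx(norm1_oracle(em), rel=1e-9, abs=1e-9)
        assert norm_index(em, 2) == pytest.approx(norm2_oracle(em), rel=1e-9, abs=1e-7)
        assert norm_index(em, 3) == pytest.approx(norm3_oracle(em), rel=1e-9, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(matrices)
    def test_spectral_below_frobenius(self, em):
        assert norm_index(em, 2) <= norm_index(em, 3) + 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(matrices, st.floats(min_value=0.01, max_value=100))
    def test_positive_homogeneity(self, em, c):
        for k in (1, 2, 3):
            assert norm_index(c * em, k) == pytest.approx(c * norm_index(em, k), rel=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            norm_index(np.zeros((0, 0)), 1)


# ---------------------------------------------------------------------------
# full descriptor vector
# ---------------------------------------------------------------------------

class TestDescriptorVector:
    def test_count_and_canonical_names(self, small_molecules):
        v = descriptor_vector(small_molecules[0])
        assert len(v.values) == 72
        assert np.all(np.isfinite(v.values)) and np.all(v.values >= 0)
        assert v.names[:3] == ("EM1_DM1_P1_norm1", "EM1_DM1_P1_norm2", "EM1_DM1_P1_norm3")
        assert v.names[-1] == "EM3_DM2_P4_norm3"
        assert len(set(DESCRIPTOR_NAMES)) == 72

    def test_permutation_invariance(self, small_molecules):
        m = small_molecules[3]
        rng = np.random.default_rng(5)
        perm = rng.permutation(m.n_atoms)
        inv = np.argsort(perm)
        relabeled = assign_charges(
            Molecule(
                id=m.id,
                elements=[m.elements[i] for i in perm],
                bonds={(inv[i], inv[j]) for i, j in m.bonds},
                coords=m.coords[perm],
                formal_charge=m.formal_charge,
            )
        )
        np.testing.assert_allclose(
            descriptor_vector(relabeled).values, descriptor_vector(m).values, rtol=1e-9, atol=1e-9
        )

    def test_rigid_motion_invariance(self, small_molecules):
        from scipy.spatial.transform import Rotation

        m = small_molecules[4]
        R = Rotation.from_euler("xyz", [1.0, 0.5, -0.7]).as_matrix()
        moved = Molecule(
            id=m.id, elements=m.elements, bonds=m.bonds,
            coords=m.coords @ R.T + 7.0, charges=m.charges, formal_charge=m.formal_charge,
        )
        np.testing.assert_allclose(
            descriptor_vector(moved).values, descriptor_vector(m).values, rtol=1e-9, atol=1e-9
        )
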