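"""Norm-index molecular descriptors.

Each molecule is reduced to 72 scalar descriptors.  Two interatomic distance
matrices are built — the step matrix ``DM1`` (graph shortest-path lengths in
bonds) and the Euclidean matrix ``DM2`` (Angstrom) — together with an N x 4
atomic property matrix ``PM`` whose columns are, in fixed order, the electron
shell number SN, Pauling electronegativity EN, first ionization energy Ei
(eV) and tanh of the partial charge.  Three extended-matrix families combine
a distance matrix DM_m with one property column p = PM(:, n):

* ``EM1`` : DM_m with p appended as an extra column (N x (N+1)),
* ``EM2`` : outer product p p^T plus DM_m,
* ``EM3`` : outer product p p^T times DM_m (elementwise by default).

Each of the 3 x 2 x 4 = 24 extended matrices is summarized by three matrix
norms — the maximum absolute column sum, the spectral norm (largest singular
value) and the Frobenius norm — giving 72 nonnegative descriptors that are
invariant to atom relabeling and to rigid motions of the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .structure_io import Molecule, lookup_properties

__all__ = [
    "DESCRIPTOR_NAMES",
    "step_matrix",
    "euclidean_matrix",
    "property_matrix",
    "extended_matrix",
    "norm_index",
    "descriptor_vector",
    "descriptor_table",
]

_FAMILIES = ("EM1", "EM2", "EM3")
_DM_INDEXES = (1, 2)
_PM_COLUMNS = (1, 2, 3, 4)
_NORMS = (1, 2, 3)

#: canonical descriptor order: family, then distance matrix, then property
#: column, then norm kind — fixes the column order of every downstream matrix
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    f"{fam}_DM{m}_P{n}_norm{k}"
    for fam in _FAMILIES
    for m in _DM_INDEXES
    for n in _PM_COLUMNS
    for k in _NORMS
)
assert len(DESCRIPTOR_NAMES) == 72


def step_matrix(mol: Molecule) -> np.ndarray:
    """Graph shortest-path length (number of bonds) between every atom pair.

    Requires a connected bond graph; raises ``ValueError`` otherwise.
    """
    n = mol.n_atoms
    if n == 1:
        return np.zeros((1, 1), dtype=int)
    adj = csr_matrix(mol.adjacency())
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(d).any():
        raise ValueError(f"molecule {mol.id!r}: bond graph is disconnected (infinite step)")
    return d.astype(int)


def euclidean_matrix(mol: Molecule) -> np.ndarray:
    """Pairwise straight-line interatomic distances in Angstrom."""
    c = np.asarray(mol.coords, dtype=float)
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def property_matrix(mol: Molecule) -> np.ndarray:
    """N x 4 matrix with columns [SN, EN, Ei, tanh(charge)] per atom."""
    if mol.charges is None:
        raise ValueError(f"molecule {mol.id!r}: charges must be assigned first")
    rows = []
    for el, q in zip(mol.elements, mol.charges):
        rec = lookup_properties(el)
        rows.append([rec.SN, rec.EN, rec.Ei, np.tanh(q)])
    return np.array(rows, dtype=float)


def extended_matrix(
    family: str, dm: np.ndarray, pm_col: np.ndarray, em3_product: str = "hadamard"
) -> np.ndarray:
    """Combine a distance matrix with one atomic-property column.

    ``EM1`` appends the column (N x (N+1)); ``EM2`` adds the outer product
    of the column to the distance matrix; ``EM3`` multiplies them.  For EM3
    the product is elementwise by default (keeps symmetry and the zero
    diagonal); ``em3_product="matmul"`` gives the matrix-product reading.
    """
    dm = np.asarray(dm, dtype=float)
    p = np.asarray(pm_col, dtype=float).ravel()
    n = dm.shape[0]
    if dm.shape != (n, n) or p.shape != (n,):
        raise ValueError(f"shape mismatch: DM {dm.shape}, property column {p.shape}")
    if family == "EM1":
        return np.hstack([dm, p[:, None]])
    outer = np.outer(p, p)
    if family == "EM2":
        return outer + dm
    if family == "EM3":
        if em3_product == "hadamard":
            return outer * dm
        if em3_product == "matmul":
            return outer @ dm
        raise ValueError(f"unknown em3_product {em3_product!r}")
    raise ValueError(f"unknown extended-matrix family {family!r}")


def norm_index(em: np.ndarray, k: int) -> float:
    """Matrix norm of an extended matrix.

    k=1: maximum over columns of the sum of absolute entries; k=2: largest
    singular value; k=3: Frobenius norm.  Valid for non-square input.
    """
    em = np.asarray(em, dtype=float)
    if em.size == 0:
        raise ValueError("empty matrix has no norm index")
    if not np.all(np.isfinite(em)):
        raise ValueError("matrix entries must be finite")
    if k == 1:
        return float(np.abs(em).sum(axis=0).max())
    if k == 2:
        return float(np.linalg.svd(em, compute_uv=False)[0])
    if k == 3:
        return float(np.sqrt((em**2).sum()))
    raise ValueError(f"norm kind must be 1, 2 or 3, got {k}")


@dataclass(frozen=True)
class DescriptorVector:
    """The 72 named norm-index descriptors of one structure."""

    id: str
    names: tuple[str, ...]
    values: np.ndarray

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def descriptor_vector(mol: Molecule, em3_product: str = "hadamard") -> DescriptorVector:
    """All 72 norm-index descriptors of one molecule, in canonical order."""
    dms = {1: step_matrix(mol).astype(float), 2: euclidean_matrix(mol)}
    pm = property_matrix(mol)
    values = np.empty(len(DESCRIPTOR_NAMES))
    idx = 0
    for fam in _FAMILIES:
        for m in _DM_INDEXES:
            for n in _PM_COLUMNS:
                em = extended_matrix(fam, dms[m], pm[:, n - 1], em3_product=em3_product)
                for k in _NORMS:
                    values[idx] = norm_index(em, k)
                    idx += 1
    if not np.all(np.isfinite(values)):
        raise ValueError(f"molecule {mol.id!r}: non-finite descriptor values")
    return DescriptorVector(id=mol.id, names=DESCRIPTOR_NAMES, values=values)


def descriptor_table(molecules: Iterable[Molecule], em3_product: str = "hadamard"):
    """Descriptor matrix for many molecules as a DataFrame indexed by id."""
    import pandas as pd

    vecs = [descriptor_vector(m, em3_product=em3_product) for m in molecules]
    df = pd.DataFrame(
        [v.values for v in vecs], columns=list(DESCRIPTOR_NAMES), index=[v.id for v in vecs]
    )
    df.index.name = "id"
    return df
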