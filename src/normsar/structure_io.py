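"""Molecular structure I/O, atomic reference properties and partial charges.

The descriptor machinery downstream needs, per molecule: element symbols
(hydrogens included), a connected bond graph, 3D Cartesian coordinates in
Angstrom and per-atom partial charges.  Structures arrive as SDF/MOL V2000,
XYZ (optional 5th column = charge) or SMILES (embedded internally).  Partial
charges are read from the file when supplied and otherwise assigned by a
deterministic electronegativity-equalization scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Molecule",
    "AtomicPropertyRecord",
    "EndpointTable",
    "StructureParseError",
    "read_structures",
    "read_endpoint_table",
    "write_sdf",
    "assign_charges",
    "lookup_properties",
    "supported_elements",
]

CHARGE_SUM_TOL = 1e-3
#: multiplier on the sum of covalent radii used for XYZ bond perception
BOND_CUTOFF_FACTOR = 1.2


class StructureParseError(ValueError):
    """A structure record could not be parsed or validated."""


@dataclass(frozen=True)
class AtomicPropertyRecord:
    """Reference values for one element.

    SN is the electron shell number (period), EN the Pauling
    electronegativity, Ei the first ionization energy in eV.
    """

    element: str
    SN: int
    EN: float
    Ei: float


def _load_property_table() -> dict:
    text = resources.files("normsar.data").joinpath("atomic_properties.json").read_text()
    return json.loads(text)["elements"]


_TABLE = _load_property_table()


def supported_elements() -> tuple[str, ...]:
    return tuple(_TABLE)


def lookup_properties(element: str) -> AtomicPropertyRecord:
    """Return the frozen (SN, EN, Ei) record for ``element``.

    Raises ``KeyError`` naming the element when it is not covered.
    """
    try:
        rec = _TABLE[element]
    except KeyError:
        raise KeyError(f"element {element!r} is not in the atomic property table") from None
    return AtomicPropertyRecord(element=element, SN=rec["SN"], EN=rec["EN"], Ei=rec["Ei"])


@dataclass
class Molecule:
    """A single covalent species: all-atom graph plus 3D geometry and charges.

    ``bonds`` is a set of index pairs (i < j) over atoms; the graph must be
    connected.  ``coords`` is N x 3 in Angstrom.  ``charges`` are partial
    atomic charges in elementary charge units, summing to ``formal_charge``.
    """

    id: str
    elements: list[str]
    bonds: set[tuple[int, int]]
    coords: np.ndarray
    charges: np.ndarray | None = None
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
        self.bonds = {(min(i, j), max(i, j)) for i, j in self.bonds}

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix over atom indices."""
        n = self.n_atoms
        A = np.zeros((n, n), dtype=int)
        for i, j in self.bonds:
            A[i, j] = A[j, i] = 1
        return A

    def validate(self) -> "Molecule":
        n = self.n_atoms
        if n == 0:
            raise StructureParseError(f"molecule {self.id!r}: no atoms")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise StructureParseError(f"molecule {self.id!r}: coords must be finite N x 3")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise StructureParseError(f"molecule {self.id!r}: bond ({i},{j}) out of range")
        if n > 1 and not _connected(n, self.bonds):
            raise StructureParseError(f"molecule {self.id!r}: bond graph is disconnected")
        if self.charges is not None:
            if self.charges.shape != (n,) or not np.all(np.isfinite(self.charges)):
                raise StructureParseError(f"molecule {self.id!r}: charges must be finite length-N")
            if abs(float(self.charges.sum()) - self.formal_charge) > CHARGE_SUM_TOL:
                raise StructureParseError(
                    f"molecule {self.id!r}: charges sum to {self.charges.sum():.4f}, "
                    f"expected formal charge {self.formal_charge}"
                )
        return self


def _connected(n: int, bonds: Iterable[tuple[int, int]]) -> bool:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    seen = {0}
    stack = [0]
    while stack:
        for k in adj[stack.pop()]:
            if k not in seen:
                seen.add(k)
                stack.append(k)
    return len(seen) == n


# ---------------------------------------------------------------------------
# partial charges: damped electronegativity equalization
# ---------------------------------------------------------------------------

_N_EEQ_ITERATIONS = 12


def assign_charges(mol: Molecule) -> Molecule:
    """Assign partial charges by damped electronegativity equalization.

    Charge flows along each bond from the less to the more electronegative
    atom, with the transferred amount damped geometrically per sweep
    (Gasteiger-style).  The scheme is deterministic, permutation-equivariant,
    idempotent (it recomputes from the graph, ignoring existing charges) and
    conserves total charge exactly: the result sums to ``formal_charge``.

    Note this is a classical stand-in for quantum-chemically derived charges;
    file-supplied charges, when present, take precedence upstream.
    """
    n = mol.n_atoms
    for el in mol.elements:
        if el not in _TABLE:
            raise KeyError(f"element {el!r} unsupported by the charge scheme")
    chi = np.array([_TABLE[el]["EN"] for el in mol.elements])
    eta = np.array([_TABLE[el]["hardness"] for el in mol.elements])
    q = np.full(n, mol.formal_charge / n, dtype=float)
    bonds = sorted(mol.bonds)
    for sweep in range(_N_EEQ_ITERATIONS):
        damping = 0.5 ** (sweep + 1)
        # effective electronegativity rises as an atom accumulates negative...
        # positive charge: chi_eff = chi + eta * q
        chi_eff = chi + eta * q
        dq = np.zeros(n)
        for i, j in bonds:
            t = damping * (chi_eff[j] - chi_eff[i]) / (eta[i] + eta[j])
            dq[i] += t
            dq[j] -= t
        q += dq
    # exact conservation against float drift
    q += (mol.formal_charge - q.sum()) / n
    out = replace(mol, charges=q)
    return out.validate()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_structures(path: str | Path, format: str | None = None) -> list[Molecule]:
    """Read molecules from an SDF, XYZ or SMILES file.

    ``format`` is one of ``{"sdf", "xyz", "smiles"}``; when omitted it is
    inferred from the file suffix.  SDF bond blocks are used verbatim; XYZ
    bonds are perceived from a covalent-radius cutoff; SMILES records are
    embedded in 3D internally.  Charges are taken from a per-atom field when
    the file carries one, otherwise assigned by :func:`assign_charges`.

    Records that fail to parse are skipped with their index reported in a
    single trailing :class:`StructureParseError` if *all* records fail;
    otherwise parse errors are collected on the returned list's
    ``.errors``-free contract: the function returns the valid molecules and
    raises only when nothing parses.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"sdf": "sdf", "mol": "sdf", "xyz": "xyz", "smi": "smiles", "smiles": "smiles"}.get(
            suffix, suffix
        )
    if format == "sdf":
        records = _read_sdf(path)
    elif format == "xyz":
        records = _read_xyz(path)
    elif format == "smiles":
        records = _read_smiles(path)
    else:
        raise ValueError(f"unknown structure format {format!r}")

    molecules: list[Molecule] = []
    errors: list[str] = []
    for idx, item in enumerate(records):
        if isinstance(item, Exception):
            errors.append(f"record {idx}: {item}")
            continue
        try:
            item.validate()
            if item.charges is None:
                item = assign_charges(item)
            molecules.append(item)
        except (StructureParseError, KeyError) as exc:
            errors.append(f"record {idx}: {exc}")
    if errors and not molecules:
        raise StructureParseError("; ".join(errors))
    if errors:
        import warnings

        warnings.warn(f"skipped {len(errors)} unparseable record(s): " + "; ".join(errors))
    return molecules


def _read_sdf(path: Path) -> list:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    out: list = []
    for rec, rdmol in enumerate(supplier):
        if rdmol is None:
            out.append(StructureParseError("rdkit failed to parse SDF record"))
            continue
        try:
            out.append(_from_rdkit(rdmol, default_id=f"mol{rec}"))
        except Exception as exc:  # noqa: BLE001 - per-record error reporting
            out.append(exc)
    return out


def _from_rdkit(rdmol, default_id: str) -> Molecule:
    from rdkit import Chem

    if rdmol.GetNumConformers() == 0:
        raise StructureParseError("no 3D coordinates in record")
    conf = rdmol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
                       for i in range(rdmol.GetNumAtoms())])
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    bonds = {(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()}
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name").strip() else default_id
    charges = None
    if rdmol.HasProp("PARTIAL_CHARGES"):
        charges = np.array([float(tok) for tok in rdmol.GetProp("PARTIAL_CHARGES").split()])
    formal = sum(a.GetFormalCharge() for a in rdmol.GetAtoms())
    return Molecule(id=name, elements=elements, bonds=bonds, coords=coords,
                    charges=charges, formal_charge=formal)


def _read_xyz(path: Path, cutoff_factor: float = BOND_CUTOFF_FACTOR) -> list:
    """Multi-record XYZ; an optional 5th column per atom line is the charge."""
    lines = Path(path).read_text().splitlines()
    out: list = []
    pos = 0
    rec = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        natoms = 0
        try:
            natoms = int(lines[pos].split()[0])
            comment = lines[pos + 1].strip() if pos + 1 < len(lines) else ""
            body = lines[pos + 2 : pos + 2 + natoms]
            if len(body) < natoms:
                raise StructureParseError("truncated XYZ record")
            elements, coords, charges = [], [], []
            has_charge = None
            for ln in body:
                toks = ln.split()
                elements.append(toks[0])
                coords.append([float(toks[1]), float(toks[2]), float(toks[3])])
                if has_charge is None:
                    has_charge = len(toks) >= 5
                if has_charge:
                    charges.append(float(toks[4]))
            coords_arr = np.array(coords)
            bonds = perceive_bonds(elements, coords_arr, cutoff_factor)
            mol = Molecule(
                id=comment or f"mol{rec}",
                elements=elements,
                bonds=bonds,
                coords=coords_arr,
                charges=np.array(charges) if has_charge else None,
                formal_charge=int(round(sum(charges))) if has_charge else 0,
            )
            out.append(mol)
        except StructureParseError as exc:
            out.append(exc)
        except (ValueError, IndexError) as exc:
            out.append(StructureParseError(f"malformed XYZ record: {exc}"))
        pos += 2 + natoms
        rec += 1
    return out


def perceive_bonds(
    elements: Sequence[str], coords: np.ndarray, cutoff_factor: float = BOND_CUTOFF_FACTOR
) -> set[tuple[int, int]]:
    """Bond two atoms when their distance < cutoff_factor * (r_i + r_j)."""
    radii = []
    for el in elements:
        if el not in _TABLE:
            raise KeyError(f"no covalent radius for element {el!r}")
        radii.append(_TABLE[el]["covalent_radius"])
    n = len(elements)
    bonds: set[tuple[int, int]] = set()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cutoff_factor * (radii[i] + radii[j]):
                bonds.add((i, j))
    return bonds


def _read_smiles(path: Path) -> list:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    out: list = []
    for rec, ln in enumerate(lines):
        parts = ln.split("\t") if "\t" in ln else ln.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{rec}"
        try:
            out.append(molecule_from_smiles(smiles, mol_id))
        except Exception as exc:  # noqa: BLE001
            out.append(StructureParseError(f"SMILES {smiles!r}: {exc}"))
    return out


def molecule_from_smiles(smiles: str, mol_id: str, seed: int = 20210410) -> Molecule:
    """Parse SMILES, add hydrogens and embed one 3D conformer (ETKDG)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise StructureParseError("rdkit failed to parse SMILES")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise StructureParseError("3D embedding failed")
    return _from_rdkit(rdmol, default_id=mol_id)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as SDF V2000 with a ``<PARTIAL_CHARGES>`` data field.

    Bond orders are not tracked by :class:`Molecule`; all bonds are written
    as single bonds, which preserves the adjacency round trip.
    """
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(_to_sdf_block(mol))


def _to_sdf_block(mol: Molecule) -> str:
    lines = [mol.id, "  normsar", ""]
    lines.append(f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in sorted(mol.bonds):
        lines.append(f"{i + 1:3d}{j + 1:3d}  1  0")
    lines.append("M  END")
    if mol.charges is not None:
        lines.append("> <PARTIAL_CHARGES>")
        lines.append(" ".join(repr(float(c)) for c in mol.charges))
        lines.append("")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# endpoint table
# ---------------------------------------------------------------------------


@dataclass
class EndpointTable:
    """Endpoint values (log10 particles per cell) keyed by structure id."""

    ids: list[str]
    uptake: np.ndarray

    def __post_init__(self) -> None:
        self.uptake = np.asarray(self.uptake, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("endpoint table ids are not unique")
        if self.uptake.shape != (len(self.ids),):
            raise ValueError("uptake length must match ids")

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.uptake.tolist()))


def read_endpoint_table(path: str | Path) -> EndpointTable:
    """Read a CSV with header ``id,uptake``."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"id", "uptake"}.issubset(df.columns):
        raise ValueError("endpoint CSV must have columns 'id' and 'uptake'")
    return EndpointTable(ids=[str(i) for i in df["id"]], uptake=df["uptake"].to_numpy(float))
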