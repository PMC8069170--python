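import numpy as np
import pytest

from normsar import Molecule, SyntheticConfig, assign_charges, generate_molecules


@pytest.fixture(scope="session")
def water():
    """O-H2 at a water-like geometry, bonds explicit."""
    coords = np.array([[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.24, 0.9266, 0.0]])
    return assign_charges(
        Molecule(id="water", elements=["O", "H", "H"], bonds={(0, 1), (0, 2)}, coords=coords)
    )


@pytest.fixture(scope="session")
def small_molecules():
    """A fixed batch of synthetic modifier molecules for descriptor tests."""
    return generate_molecules(SyntheticConfig(n_molecules=6, heavy_atom_range=(5, 14), seed=11))


def chain_molecule(elements, bond_length=1.5, mol_id="chain"):
    """Linear chain with unit spacing along x; charges assigned."""
    n = len(elements)
    coords = np.column_stack([np.arange(n) * bond_length, np.zeros(n), np.zeros(n)])
    bonds = {(i, i + 1) for i in range(n - 1)}
    return assign_charges(Molecule(id=mol_id, elements=list(elements), bonds=bonds, coords=coords))
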