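import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from chemprof import attach_descriptors, boundary_fixture_library
from chemprof.chemio import MoleculeRecord


@pytest.fixture(scope="session")
def boundary():
    """The shipped fixture panel: (library, truths for the vector records)."""
    return boundary_fixture_library()


@pytest.fixture(scope="session")
def boundary_descriptors(boundary):
    lib, _truths = boundary
    return attach_descriptors(lib)


def make_3d_record(smiles: str, record_id: str = "mol") -> MoleculeRecord:
    """Embed a deterministic 3D conformer (explicit hydrogens)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 0xF00D
    assert AllChem.EmbedMolecule(mol, params) == 0
    return MoleculeRecord(record_id=record_id, title=record_id, mol=mol)


def methane_record() -> MoleculeRecord:
    """Methane with a fixed ideal tetrahedral geometry (C-H 1.09 A)."""
    mol = Chem.AddHs(Chem.MolFromSmiles("C"))
    conf = Chem.Conformer(mol.GetNumAtoms())
    d = 1.09 / np.sqrt(3.0)
    coords = [(0.0, 0.0, 0.0), (d, d, d), (d, -d, -d), (-d, d, -d), (-d, -d, d)]
    for i, (x, y, z) in enumerate(coords):
        conf.SetAtomPosition(i, (x, y, z))
    conf.Set3D(True)
    mol.AddConformer(conf)
    return MoleculeRecord(record_id="methane", title="methane", mol=mol)
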