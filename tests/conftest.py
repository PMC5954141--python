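import numpy as np
import pytest

from chemibody import MolecularGraph, make_toy_complex, read_structure, write_pdb
from chemibody.synthetic import ToyComplexSpec


@pytest.fixture(scope="session")
def toy_complex(tmp_path_factory):
    """Default toy complex, written to PDB and re-read (exercises I/O)."""
    s, truth = make_toy_complex(ToyComplexSpec(seed=0))
    path = tmp_path_factory.mktemp("toy") / "complex.pdb"
    write_pdb(s, path)
    return read_structure(path), truth


@pytest.fixture(scope="session")
def butane_graph():
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles("CCCC")
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=0)
    AllChem.MMFFOptimizeMolecule(mol)
    return MolecularGraph(mol=mol, anchor_tags={})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
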