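import numpy as np
import pytest

from allomap.fixtures import make_shell_structure, shell_feature_table
from allomap.site_classifier import train_adaboost
from allomap.structure_io import Atom, ProteinStructure, ResidueId


def toy_structure(positions, names=None, chain="A"):
    """Structure with one CA pseudo-atom per residue at given positions."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    names = names or ["ALA"] * n
    residues, atoms = [], {}
    for i, (pos, name) in enumerate(zip(positions, names)):
        rid = ResidueId(chain, i + 1, "", name)
        residues.append(rid)
        atoms[rid] = (Atom("CA", "C", tuple(pos), 1.0, 10.0),)
    return ProteinStructure(
        residues=residues, coords=positions, atoms=atoms,
        bfactors=np.full(n, 10.0), chains={chain: "A" * n},
        ligands=[], source_label="toy",
    )


@pytest.fixture(scope="session")
def shell_holo():
    """Shell fixture with a surface-bound ligand and its planted truth."""
    return make_shell_structure(seed=3, ligand="surface")


@pytest.fixture(scope="session")
def shell_model():
    """Classifier trained on features computed from shell fixtures."""
    table = shell_feature_table(range(8))
    return train_adaboost(table, n_rounds=20, seed=0)
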