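import numpy as np
import pytest

from vdyn import (
    make_toy_chain,
    random_orthonormal_modes,
    sample_gaussian_trajectory,
    select_atoms,
)

#: handcrafted three-atom single-residue PDB used across I/O tests
THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   3.500   3.000  1.00  0.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def toy_chain():
    return make_toy_chain(10)


@pytest.fixture
def toy_backbone_chain():
    return make_toy_chain(10, backbone=True)


@pytest.fixture
def planted_trajectory(toy_chain):
    """Gaussian ensemble with 3 planted modes (lambda = 9, 4, 1 A^2)."""
    eigenvalues = np.array([9.0, 4.0, 1.0])
    modes = random_orthonormal_modes(3 * toy_chain.n_atoms, 3, seed=7)
    traj = sample_gaussian_trajectory(toy_chain, modes, eigenvalues, 4000, seed=8)
    return traj, modes, eigenvalues


@pytest.fixture
def ca_selection(toy_chain):
    return select_atoms(toy_chain, "ca")
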