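import numpy as np
import pytest

from gridock import LigandSpec, make_synthetic_complex
from gridock.model import Molecule, Receptor


@pytest.fixture(scope="session")
def rod_complex():
    return make_synthetic_complex(
        "rod_channel", LigandSpec(n_atoms=8, shape="rod", n_rotatable=0),
        seed=1)


@pytest.fixture(scope="session")
def imprint_complex():
    return make_synthetic_complex(
        "imprint", LigandSpec(n_atoms=8, shape="bent", n_rotatable=2),
        seed=11)


@pytest.fixture
def random_receptor():
    """Factory: a compact pseudo-receptor of random heavy atoms, roughly
    half backbone-flagged."""

    def make(n_atoms=30, seed=0, box=8.0):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-box / 2, box / 2, size=(n_atoms, 3))
        backbone = rng.random(n_atoms) < 0.5
        elements = ["C"] * n_atoms
        return Receptor(
            elements=elements,
            coords=coords,
            backbone_mask=backbone,
            atom_names=["CA" if b else "CB" for b in backbone],
            res_names=["GLY"] * n_atoms,
            res_ids=list(range(1, n_atoms + 1)),
            chain_ids=["A"] * n_atoms,
        )

    return make


@pytest.fixture
def random_molecule():
    """Factory: a random all-carbon chain molecule."""

    def make(n_atoms=8, seed=0):
        rng = np.random.default_rng(seed)
        coords = np.cumsum(
            rng.normal(scale=1.0, size=(n_atoms, 3)), axis=0)
        bonds = [(i, i + 1, 1) for i in range(n_atoms - 1)]
        return Molecule(elements=["C"] * n_atoms, conformers=[coords],
                        bonds=bonds)

    return make


TOY_PDB = """\
ATOM      1  N   ALA A   1      -1.204   0.514   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.700  1.00  0.00           C
ATOM      3  C   ALA A   1       1.200   0.800   0.200  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   1.900   0.750  1.00  0.00           O
ATOM      5  CB  ALA A   1       0.100  -1.500   0.500  1.00  0.00           C
ATOM      6  H   ALA A   1      -1.300   1.400   0.300  1.00  0.00           H
ATOM      7  N   SER A   2       2.204   0.514   3.000  1.00  0.00           N
ATOM      8  CA  SER A   2       3.408   0.000   3.700  1.00  0.00           C
ATOM      9  C   SER A   2       4.608   0.800   3.200  1.00  0.00           C
ATOM     10  O   SER A   2       4.708   1.900   3.750  1.00  0.00           O
ATOM     11  CB  SER A   2       3.508  -1.500   3.500  1.00  0.00           C
ATOM     12  OG  SER A   2       3.608  -2.200   4.700  1.00  0.00           O
ATOM     13  N   LEU A   3       5.204   0.514   6.000  1.00  0.00           N
ATOM     14  CA  LEU A   3       6.408   0.000   6.700  1.00  0.00           C
ATOM     15  C   LEU A   3       7.608   0.800   6.200  1.00  0.00           C
ATOM     16  O   LEU A   3       7.708   1.900   6.750  1.00  0.00           O
ATOM     17  CB  LEU A   3       6.508  -1.500   6.500  1.00  0.00           C
ATOM     18  CG  LEU A   3       7.008  -2.300   7.700  1.00  0.00           C
ATOM     19  CD1 LEU A   3       7.108  -3.800   7.400  1.00  0.00           C
ATOM     20  CD2 LEU A   3       8.408  -1.800   8.100  1.00  0.00           C
ATOM     21  CD3 LEU A   3       9.008  -2.700   9.100  1.00  0.00           C
HETATM   22  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
HETATM   23  O   HOH A 102      11.000  11.000  11.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


BUTANE_SDF = """\
butane
  test

  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    1.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.5000    1.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
M  END
$$$$
"""

BENZENE_SDF = """\
benzene
  test

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950    1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950    1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.3900    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6950   -1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6950   -1.2037    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  3  4  1  0
  4  5  1  0
  5  6  1  0
  6  1  1  0
M  END
$$$$
"""


@pytest.fixture
def butane_sdf(tmp_path):
    path = tmp_path / "butane.sdf"
    path.write_text(BUTANE_SDF)
    return path


@pytest.fixture
def benzene_sdf(tmp_path):
    path = tmp_path / "benzene.sdf"
    path.write_text(BENZENE_SDF)
    return path
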