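import numpy as np
import pytest

from cmap2struct import cmap as cmap_mod
from cmap2struct import fixtures
from cmap2struct.structio import extract_ca_trace


@pytest.fixture(scope="session")
def helix30():
    return fixtures.make_ideal_helix(30)


@pytest.fixture(scope="session")
def helix30_map(helix30):
    return cmap_mod.derive_cmap(helix30, threshold=8.0, atom_mode="CA")


@pytest.fixture(scope="session")
def coil60():
    return fixtures.make_compact_coil(60, seed=3)


@pytest.fixture(scope="session")
def coil60_map(coil60):
    return cmap_mod.derive_cmap(coil60, threshold=8.0, atom_mode="CA")


@pytest.fixture(scope="session")
def tetramer14():
    return fixtures.make_toy_tetramer(14, pore_radius=5.0)


@pytest.fixture(scope="session")
def tetramer14_map(tetramer14):
    return cmap_mod.derive_cmap(tetramer14, threshold=8.0, atom_mode="CA")


def random_ternary_map(L: int, seed: int, unknown_frac: float = 0.2) -> cmap_mod.ContactMap:
    """Random symmetric ternary matrix (test utility, not a package op)."""
    rng = np.random.default_rng(seed)
    M = rng.choice([1, 0, -1], size=(L, L), p=[0.3, 0.7 - unknown_frac, unknown_frac])
    M = np.triu(M, 1)
    M = M + M.T
    np.fill_diagonal(M, 1)
    return cmap_mod.ContactMap(M)


PDB_3RES = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.331  -5.837  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.247   4.690  -4.881  1.00  0.00           C
ATOM      6  N   GLY A   2      12.635   7.881  -3.861  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.600   8.950  -3.596  1.00  0.00           C
ATOM      8  C   GLY A   2      13.092  10.304  -4.083  1.00  0.00           C
ATOM      9  O   GLY A   2      11.898  10.549  -4.195  1.00  0.00           O
ATOM     10  N   SER A   3      14.025  11.195  -4.392  1.00  0.00           N
ATOM     11  CA  SER A   3      13.690  12.531  -4.876  1.00  0.00           C
ATOM     12  C   SER A   3      13.069  13.397  -3.781  1.00  0.00           C
ATOM     13  O   SER A   3      12.361  14.361  -4.075  1.00  0.00           O
ATOM     14  OG  SER A   3      14.665  13.145  -5.698  1.00  0.00           O
TER
END
"""


@pytest.fixture()
def pdb_3res(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(PDB_3RES)
    return path
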