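import numpy as np
import pytest

from docktriage.struct_io import AtomRecord, MolecularGraph


def hexagon_graph(rotation_deg: float = 0.0, bond_length: float = 1.39) -> MolecularGraph:
    """An ideal all-carbon six-ring in the xy-plane (circumradius = bond length)."""
    angles = np.radians(60.0 * np.arange(6) + rotation_deg)
    xyz = bond_length * np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
    atoms = [AtomRecord("C", f"C{i + 1}", xyz[i], False) for i in range(6)]
    return MolecularGraph(atoms=atoms, bonds={(i, (i + 1) % 6) for i in range(6)})


@pytest.fixture
def benzene_pair():
    """The same carbon ring and a copy rotated 60° about its normal."""
    return hexagon_graph(0.0), hexagon_graph(60.0)


ALANINE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.345   7.364  -4.803  1.00  0.00           C
ATOM      4  O   ALA A   1      12.462   8.234  -5.659  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.597   4.895  -5.063  1.00  0.00           C
END
"""

ETHANOL_SDF = """\
ethanol heavy atoms
  synthetic

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    1.3000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
"""

ETHANOL_MOL2 = """\
@<TRIPOS>MOLECULE
ethanol heavy atoms
 3 2 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1          0.0000    0.0000    0.0000 C.3     1  LIG1        0.0000
      2 C2          1.5000    0.0000    0.0000 C.3     1  LIG1        0.0000
      3 O1          2.0000    1.3000    0.0000 O.3     1  LIG1        0.0000
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
"""
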