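import numpy as np
import pytest

from tmimpact.fixtures import FixtureSpec, build_fixture
from tmimpact.placement import CORE, MembranePlacement


@pytest.fixture(scope="session")
def helix20():
    """Ideal vertical TM helix: Leu core, Lys anchors, 20 residues."""
    s, truth = build_fixture(FixtureSpec(kind="ideal_helix", length=20))
    return s, truth


@pytest.fixture(scope="session")
def helix22():
    """22-mer whose terminal lysines sit in the headgroup belt."""
    s, truth = build_fixture(FixtureSpec(kind="ideal_helix", length=22))
    return s, truth


def forced_placement(s, region=CORE, overrides=None):
    """A hand-built placement labelling every residue `region` (evaluator
    unit tests bypass the grid search with this)."""
    pl = MembranePlacement(0.0, 0.0, 0.0, 0.0, n_grid_points=0)
    pl.region_of = {r.selector: region for r in s.residues(amino_only=True)}
    if overrides:
        pl.region_of.update(overrides)
    return pl


MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.895  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.406  -5.734  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.542   6.230  -4.096  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  SER A   1       2.000  -0.760  -1.220  1.00  0.00           C
ATOM      6  OG ASER A   1       1.500  -2.080  -1.250  0.60  0.00           O
ATOM      7  OG BSER A   1       3.420  -0.800  -1.200  0.40  0.00           O
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(MINIMAL_ALA_PDB)
    return p


@pytest.fixture()
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def all_coords(s):
    return np.array([a.coord for r in s.residues() for a in r.atoms])
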