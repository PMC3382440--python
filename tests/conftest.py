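import numpy as np
import pytest

from bsfinder.pipeline import RunConfig
from bsfinder.synth import PALETTE_B, SynthSpec, plant_shared_site

GLY_ALA_GLY_PDB = """\
HEADER    TEST FIXTURE
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   ALA A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM      9  CB  ALA A   2       3.524   3.655   1.203  1.00  0.00           C
ATOM     10  N   GLY A   3       6.224   3.807   0.000  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.681   3.781   0.000  1.00  0.00           C
ATOM     12  C   GLY A   3       8.288   5.174   0.000  1.00  0.00           C
ATOM     13  O   GLY A   3       7.588   6.184   0.000  1.00  0.00           O
TER
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
TER
ATOM      5  N   ALA B   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  ALA B   1      11.458   0.000   0.000  1.00  0.00           C
ATOM      7  C   ALA B   1      12.009   1.420   0.000  1.00  0.00           C
ATOM      8  O   ALA B   1      11.251   2.390   0.000  1.00  0.00           O
ATOM      9  CB  ALA B   1      10.994  -0.771  -1.203  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB ASER A   1       2.000  -0.800   1.200  0.60  0.00           C
ATOM      6  CB BSER A   1       2.100  -0.900   1.100  0.40  0.00           C
ATOM      7  OG ASER A   1       1.500  -2.100   1.300  0.60  0.00           O
ATOM      8  OG BSER A   1       1.600  -2.200   1.200  0.40  0.00           O
TER
END
"""


@pytest.fixture
def gly_ala_gly(tmp_path):
    p = tmp_path / "gag.pdb"
    p.write_text(GLY_ALA_GLY_PDB)
    return p


@pytest.fixture
def two_chain(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def planted_pair():
    """One surface-planted synthetic pair shared by the pipeline tests."""
    A, B, truth = plant_shared_site(
        SynthSpec(seed=11), SynthSpec(seed=12, residue_palette=list(PALETTE_B))
    )
    return A, B, truth


@pytest.fixture(scope="session")
def planted_reports(planted_pair):
    from bsfinder.pipeline import compare_structures

    A, B, truth = planted_pair
    return compare_structures(A, B, RunConfig())


def random_atom_cloud(rng, n, box=6.0, min_dist=1.0):
    """n random points in a box with a minimum separation (rejection)."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(0.0, box, size=3)
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_dist:
            continue
        pts.append(p)
    return np.array(pts)
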