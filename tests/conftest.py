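import numpy as np
import pytest

from epigrid.benchmarks import fixture_cei_table, reference_potential
from epigrid.fixtures import FixtureSpec, make_toy_antigen

ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.986  -0.773  -1.199  1.00  0.00           C
END
"""

ALA_HOH_PDB = ALA_PDB.replace(
    "END\n",
    "HETATM    6  O   HOH A 101       8.000   8.000   8.000  1.00  0.00           O\nEND\n",
)

ALA_ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB AALA A   1       1.986  -0.773  -1.199  0.50  0.00           C
ATOM      6  CB BALA A   1       1.900  -0.700  -1.100  0.50  0.00           C
END
"""


@pytest.fixture(scope="session")
def potential():
    return reference_potential(seed=11)


@pytest.fixture(scope="session")
def cei_table():
    return fixture_cei_table(seed=12)


@pytest.fixture(scope="session")
def toy_antigen():
    return make_toy_antigen(FixtureSpec(n_residues=30, seed=7))


def random_point_structure(n_atoms, seed, box=6.0):
    """Tiny pseudo-structure of isolated alanine CB 'atoms' for morphology oracles."""
    from epigrid.structure_io import Atom, Residue, Structure

    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_atoms):
        key = ("A", i + 1, "")
        pos = rng.uniform(0, box, size=3)
        vdw = float(rng.uniform(1.4, 1.9))
        residues.append(
            Residue(
                residue_key=key,
                amino_acid="A",
                atoms=[
                    Atom(serial=i + 1, name="CB", element="C", residue_key=key,
                         position=pos, vdw_radius=vdw, is_heavy=True,
                         is_side_chain=True)
                ],
                sequence_index=i,
            )
        )
    return Structure(pdb_id=f"RND{seed}", chain_id="A", residues=residues)
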