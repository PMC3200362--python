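import numpy as np
import pytest

from protpka.solver import DielectricEnvironment
from protpka.structure import Atom, Structure

#: coarse-but-adequate focusing settings for tests that only need physical
#: trends or exact cancellations, not sub-percent solver accuracy
CHEAP = dict(levels=[1.5, 0.5], npoints_cap=53, tol=1e-6)


@pytest.fixture
def env_uniform():
    """Uniform solvent dielectric: protein eps equals water eps."""
    return DielectricEnvironment(eps_protein=80.0, eps_water=80.0, ionic_strength=0.0)


@pytest.fixture
def env_default():
    return DielectricEnvironment()


def atom(name, xyz, element=None, resname="MAT", chain="X", resseq=1, **kw):
    return Atom(
        serial=0,
        name=name,
        element=element or name[0],
        resname=resname,
        chain=chain,
        resseq=resseq,
        xyz=np.asarray(xyz, dtype=float),
        **kw,
    )


def bare_structure(*atoms):
    return Structure(atoms=list(atoms))


FOUR_ATOM_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.005   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  CB ASER A   1       2.000   1.400   0.100  0.60  0.00           C
ATOM      4  CB BSER A   1       2.100   1.300  -0.500  0.40  0.00           C
ATOM      5  OG ASER A   1       3.400   1.400   0.100  0.60  0.00           O
ATOM      6  OG BSER A   1       3.500   1.300  -0.500  0.40  0.00           O
HETATM    7  O   HOH W   1       5.000   0.000   0.000  1.00  0.00           O
HETATM    8  O   HOH W   2       8.000   0.000   0.000  1.00  0.00           O
HETATM    9  O   HOH W   3      11.000   0.000   0.000  1.00  0.00           O
END
"""
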