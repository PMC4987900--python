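import numpy as np
import pytest

from confstats.builder import ChainSpec, FamilySpec, build_chain, build_ensemble

# A small hand-written PDB exercising the parsing policies: two models,
# an altloc pair, and two chains.
TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60 11.00           C
ATOM      3  CA BALA A   1      12.000   6.100  -5.000  0.40 12.00           C
ATOM      4  C   ALA A   1      10.674   6.715  -4.147  1.00 13.00           C
ATOM      5  O   ALA A   1       9.462   6.650  -4.332  1.00 14.00           O
ATOM      6  N   GLY A   2      11.211   7.359  -3.103  1.00 15.00           N
ATOM      7  CA  GLY A   2      10.411   8.036  -2.080  1.00 16.00           C
ATOM      8  C   GLY A   2      11.104   8.078  -0.720  1.00 17.00           C
ATOM      9  O   GLY A   2      12.339   8.060  -0.642  1.00 18.00           O
ATOM     10  N   PHE B  10      10.354   8.131   0.371  1.00 19.00           N
ATOM     11  CA  PHE B  10      10.890   8.166   1.736  1.00 20.00           C
ATOM     12  C   PHE B  10       9.830   8.790   2.646  1.00 21.00           C
ATOM     13  O   PHE B  10       8.634   8.720   2.365  1.00 22.00           O
ENDMDL
MODEL        2
ATOM     14  N   ALA A   1      99.000  99.000  99.000  1.00 10.00           N
ATOM     15  CA  ALA A   1      98.000  98.000  98.000  1.00 11.00           C
ENDMDL
END
"""

HELIX = dict(phi=-57.0, psi=-47.0, omega=180.0)


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "twomodel.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path


@pytest.fixture
def helix():
    """A 12-residue mixed-sequence ideal helix with set chi angles."""
    return build_chain(ChainSpec(sequence="AGKFSEDLTRVM",
                                 chi={2: [-60.0, 180.0, 180.0, 60.0]},
                                 **HELIX))


def two_family_ensemble(seed=7, n=10, sd=5.0):
    """Two conformational families separated by 120 deg in phi and psi
    over positions 9-13, within-family wrapped-normal sd 5 deg."""
    nres = 20
    offsets = np.zeros(nres)
    offsets[8:13] = 120.0
    base = ChainSpec(sequence="AKLSEDTFRVMAKLSEDTFR", perturbation_sd=sd,
                     seed=seed, **HELIX)
    fams = [FamilySpec("closed"), FamilySpec("open", {"phi": offsets,
                                                      "psi": offsets})]
    return build_ensemble(base, n, fams, seed=seed)


@pytest.fixture
def ensemble2fam():
    return two_family_ensemble()
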