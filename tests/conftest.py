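import numpy as np
import pytest

from rna3dcons.synthetic import FoldSpec, Segment, generate_decoy_set, generate_fold

TOY_PDB = """HEADER    RNA                                     01-JAN-10   1ABC
EXPDTA    X-RAY DIFFRACTION
REMARK   2 RESOLUTION.    2.40 ANGSTROMS.
ATOM      1  C3'   A A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  C3'   C A   2       0.000   0.000   6.000  1.00  0.00           C
ATOM      3  C3'   G A   3       0.000   0.000  12.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb() -> str:
    return TOY_PDB


@pytest.fixture
def hairpin():
    """A 10-bp stem closed by a 4-nt loop: 24 nt, 10 known pairs."""
    spec = FoldSpec([Segment("stem", 10, 0), Segment("loop", 4),
                     Segment("stem", 10, 0)], seed=1)
    return generate_fold(spec)


@pytest.fixture(scope="session")
def folds20():
    """20 generated folds with their constructed pairings."""
    return generate_decoy_set(20, (40, 160), seed=11, prefix="f20_")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
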