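import numpy as np
import pytest

from hemegate.synthetic import (
    Site2Excursion,
    SwingPlan,
    SyntheticSystemSpec,
    generate_synthetic_system,
)


SMALL_SPEC = SyntheticSystemSpec(
    n_replicates=2,
    replicate_lengths_ns=(40.0, 36.0),
    swing_plan=(SwingPlan(0, "A", 8.0, 20.0), SwingPlan(1, "B", 12.0, None)),
    site2_excursion=Site2Excursion(replicate_index=1, t_center_ns=18.0, peak_nm=1.15, width_ns=1.5),
)


@pytest.fixture(scope="session")
def small_system(tmp_path_factory):
    """A 2-replicate, 40 ns synthetic system shared across tests."""
    out = tmp_path_factory.mktemp("small_system")
    return generate_synthetic_system(out, SMALL_SPEC, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


MINI_POCKET_PDB = """\
ATOM      1  N   HIS A   1      10.000  10.000  15.000  1.00  0.00           N
ATOM      2  CA  HIS A   1      11.000  10.000  15.500  1.00  0.00           C
ATOM      3  NE2 HIS A   1      10.000  10.000  12.100  1.00  0.00           N
ATOM      4  N   HIS A   2       4.000  10.000  13.000  1.00  0.00           N
ATOM      5  CA  HIS A   2       3.500  10.000  13.500  1.00  0.00           C
ATOM      6  NE2 HIS A   2       6.000  10.000  14.000  1.00  0.00           N
HETATM    7 FE   HEM A   9      10.000  10.000  10.400  1.00  0.00          FE
HETATM    8  NA  HEM A   9      12.000  10.000  10.000  1.00  0.00           N
HETATM    9  NB  HEM A   9      10.000  12.000  10.000  1.00  0.00           N
HETATM   10  NC  HEM A   9       8.000  10.000  10.000  1.00  0.00           N
HETATM   11  ND  HEM A   9      10.000   8.000  10.000  1.00  0.00           N
END
"""


@pytest.fixture
def mini_pocket_pdb(tmp_path):
    """Fe + 4 pyrrole N + proximal/distal His: the smallest valid pocket."""
    path = tmp_path / "mini_pocket.pdb"
    path.write_text(MINI_POCKET_PDB)
    return path
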