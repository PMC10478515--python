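import numpy as np
import pytest

from speckfew.simulator import (
    BeamProfile,
    DetectorGeometry,
    random_particle,
)


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale detector for oracle comparisons (32x32 pixels)."""
    return DetectorGeometry(n_rows=32, n_cols=32)


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def beam():
    return BeamProfile()


@pytest.fixture(scope="session")
def toy_particle():
    return random_particle(50, 25.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pdb_fixture(tmp_path_factory):
    """Hand-written 4-atom PDB file (3 ATOM + 1 HETATM records)."""
    text = (
        "HEADER    SYNTHETIC FIXTURE\n"
        "ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       4.500  -1.250   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1      -2.000   0.750   5.500  1.00  0.00           C\n"
        "HETATM    4  O   HOH A   2       0.000   0.000  -1.000  1.00  0.00           O\n"
        "END\n"
    )
    path = tmp_path_factory.mktemp("pdb") / "synthetic_fixture.pdb"
    path.write_text(text)
    return path
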