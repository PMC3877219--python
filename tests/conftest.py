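import numpy as np
import pytest

from amideshift.fixtures import make_peptide
from amideshift.params import ParameterSet


@pytest.fixture(scope="session")
def params():
    return ParameterSet.default()


@pytest.fixture(scope="session")
def helix12():
    return make_peptide(12, -57.0, -47.0)


@pytest.fixture(scope="session")
def sheet6():
    return make_peptide(6, -139.0, 135.0)


def random_rigid_motion(seed):
    """A random rotation matrix (QR-based, det +1) and translation."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=20.0, size=3)
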