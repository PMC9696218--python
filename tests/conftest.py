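import numpy as np
import pytest

from dnabuckle import BucklingModel, DnaGeometry, EndConstraint, Medium


@pytest.fixture(scope="session")
def geom():
    return DnaGeometry()


@pytest.fixture(scope="session")
def medium_0p1M():
    """0.1 M monovalent salt at 298 K, the reference condition."""
    return Medium(c=0.1, Z=1, T=298.0)


@pytest.fixture(scope="session")
def suspended_model():
    """Class-mean parameters for DNA suspended in bulk solution."""
    return BucklingModel(EndConstraint(1.021), 5.95e-9)


@pytest.fixture(scope="session")
def fixbead_model():
    """Class-mean parameters for DNA with one end fixed, one on a bead."""
    return BucklingModel(EndConstraint(0.718), 8.43e-9)


@pytest.fixture(scope="session")
def salt_scan():
    """Concentration grid covering the modeled monovalent range."""
    return np.geomspace(0.001, 4.0, 60)
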