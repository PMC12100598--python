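import numpy as np
import pytest

from tubulaxs.scattering import SAXSCurve, debye_intensity, default_q_grid
from tubulaxs.synthetic_data import make_synthetic_dimer


@pytest.fixture(scope="session")
def q60():
    """A modest log-spaced q grid used across the suite (nm^-1)."""
    return default_q_grid(0.02, 3.0, 60)


@pytest.fixture(scope="session")
def coarse_dimer():
    """A cheap synthetic dimer (few beads) for assembly-level tests."""
    return make_synthetic_dimer(bead_radius=0.7)


@pytest.fixture(scope="session")
def dimer_curve(q60, coarse_dimer):
    return debye_intensity(coarse_dimer, q60)


@pytest.fixture(scope="session")
def two_bases(q60):
    """Two clearly distinct analytic basis curves on the shared grid."""
    a = SAXSCurve(q60, 1.0 / (1.0 + (q60 * 4.0) ** 2) ** 2)
    b = SAXSCurve(q60, np.exp(-((q60 * 2.5) ** 2) / 3.0) * (1.0 + 0.3 * np.cos(q60 * 8.0)))
    return a, b
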