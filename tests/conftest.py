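import numpy as np
import pytest

from hydrodr.calibration import CalibrationSet, ReflectionRecord
from hydrodr.models import FrequencyGrid, single_debye


@pytest.fixture
def grid():
    """The measured microwave band: 201 log-spaced points, 0.1-14 GHz."""
    return FrequencyGrid.log_spaced(0.1e9, 14e9, 201)


@pytest.fixture
def debye_91(grid):
    """Noiseless single-Debye spectrum with the 9.1 wt% slow-water limits."""
    return single_debye(68.59, 5.28, 5.88e-11, grid)


@pytest.fixture
def debye_29(grid):
    """Noiseless single-Debye spectrum with the 2.9 wt% slow-water limits."""
    return single_debye(76.55, 5.49, 5.88e-11, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def mobius_cal(grid, a=1.0, b=0.0, c=0.0, d=1.0, eps_a=80.0 + 0j):
    """Calibration set whose anchors come from the bilinear probe map
    S(eps) = (a eps + b) / (c eps + d); the default is the identity-like
    map used only to carry anchors."""

    def s_of(eps):
        return (a * eps + b) / (c * eps + d)

    n = len(grid)
    so = np.full(n, s_of(1.0 + 0j))
    ss = np.full(n, a / c if c != 0 else np.inf)
    sa = np.full(n, s_of(eps_a))
    std_eps_vals = np.full(n, eps_a)
    from hydrodr.models import ComplexPermittivitySpectrum

    std_eps = ComplexPermittivitySpectrum.from_complex(grid, std_eps_vals)
    return CalibrationSet(
        ReflectionRecord(grid, so, validate_passive=False),
        ReflectionRecord(grid, ss, validate_passive=False),
        ReflectionRecord(grid, sa, validate_passive=False),
        std_eps,
    )
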