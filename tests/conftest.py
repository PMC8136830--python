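import numpy as np
import pytest

from circuitfca import HillPut, MolecularParams


@pytest.fixture
def put():
    """Reference promoter under test: basal 0.1, Hill coefficient 1.5."""
    return HillPut(beta=0.1, n=1.5)


@pytest.fixture
def mol_defaults():
    """Reference molecular parameter set (beta=0.1, alpha=10, n=1.5, m=h=1)."""
    return MolecularParams()


@pytest.fixture
def wide_log_grid():
    """Input grid wide enough that both limits are saturated to <1e-5."""
    return np.geomspace(1e-4, 1e6, 601)


def dnf_quadratic_root(A: float, fs: float) -> float:
    """Independent closed-form oracle for the DNF fixed point at m=h=1.

    Substituting y = fs/(1+z) into z = A/(1+y) gives
    z**2 + z*(1 + fs - A) - A = 0; the positive root is the steady state.
    """
    b = 1.0 + fs - A
    return (-b + np.sqrt(b * b + 4.0 * A)) / 2.0
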