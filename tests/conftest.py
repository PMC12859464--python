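"""Shared fixtures: the generic study system and the weak-coupling
cross-validation setup (off-resonant bath, Eren/Omega = 0.01)."""

import numpy as np
import pytest

from blochcorridor.bath import BathSpec
from blochcorridor.model import (
    CouplingSpec,
    SystemParams,
    build_coupling_operator,
    diagonalize,
    eigen_lindblads,
)


@pytest.fixture(scope="session")
def system():
    return SystemParams(epsilon=0.5, delta=1.0)


@pytest.fixture(scope="session")
def basis(system):
    return diagonalize(system)


@pytest.fixture(scope="session")
def sigma_x_channels(basis):
    L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
    return eigen_lindblads(L, basis)


@pytest.fixture(scope="session")
def generic_bath():
    """The dimensionless study bath (energies in Delta)."""
    return BathSpec(lam=1.0, gamma=1.0, omega0=3.0, T=3.0)


@pytest.fixture(scope="session")
def weak_bath(basis):
    """Off-resonant weak-coupling bath with Eren_eff/Omega = 0.01."""
    w0 = 5.0
    lam = float(np.sqrt(0.01 * basis.Omega * 2.0 * w0**2 / np.pi))
    return BathSpec(lam=lam, gamma=0.5, omega0=w0, T=3.0)
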