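import math

import numpy as np
import pytest

from transneuron.core import CircuitParams, DeviceParams
from transneuron.potential import PotentialSpec
from transneuron.reference import reference_circuit, reference_device


@pytest.fixture(scope="session")
def device():
    return reference_device()

@pytest.fixture(scope="session")
def circuit():
    return reference_circuit()


@pytest.fixture(scope="session")
def harmonic_device():
    """Harmonic well U = k x^2 / 2 (k = 1) in a wide gap; q = 0 so the
    cluster is a free Ornstein-Uhlenbeck particle."""
    pot = PotentialSpec(kind="polynomial", coefficients=[0.0, 0.0, 0.5],
                        well_position=0.0)
    return DeviceParams(R_t=0.01 * math.exp(-10.0), lambda_=0.1, L=2.0,
                        eta=1.0, q=0.0, q_T=0.0, C_th=1e4, kappa=0.2,
                        k_B=1.0, potential=pot)


@pytest.fixture(scope="session")
def noiseless_circuit():
    return CircuitParams(R_ext=1.0, C=1.0, D_V=0.0)
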