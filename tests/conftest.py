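import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from gnpneuro.constants import DEFAULT_CONSTANTS
from gnpneuro.core_gnp import IonSpecies


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def phys_ions():
    """Physiological ion set at the canonical reference concentrations."""
    return {
        "K": IonSpecies("K", 1, 96.83, 3.17, sigma=100.0),
        "Na": IonSpecies("Na", 1, 23.58, 131.42, sigma=155.0),
        "Cl": IonSpecies("Cl", -1, 10.41, 134.59, sigma=145.0),
    }


def quad_harmonic_mean(ion, v_mV, constants, n=20001):
    """Independent oracle: numerical quadrature of d / ∫ dx/c(x) over the
    constant-field intramembrane profile, evaluated directly from the
    profile formula (midpoint rule on 1/c)."""
    u = ion.z * v_mV / constants.vt_mV
    xi = (np.arange(n) + 0.5) / n
    if abs(u) < 1e-12:
        c = ion.c_out + (ion.c_in - ion.c_out) * xi
    else:
        c = ion.c_out + (ion.c_in - ion.c_out) * np.expm1(-u * xi) / np.expm1(-u)
    return 1.0 / np.mean(1.0 / c)
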