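import numpy as np
import pytest

from imsmetry import AsymmetricWaveform, GasState, IonSpecies

# CODATA 2014 values, written out independently of the package's registry
KB = 1.38064852e-23
E_CHARGE = 1.6021766208e-19
DALTON = 1.660539040e-27
N2_MASS = 28.0134


@pytest.fixture
def n2_low_pressure():
    """Nitrogen drift gas at reduced pressure, ambient temperature."""
    return GasState.pure("N2", temperature=298.0, pressure=530.0)


@pytest.fixture
def n2_ambient():
    return GasState.pure("N2", temperature=298.0, pressure=101325.0)


@pytest.fixture
def peptide_ion():
    return IonSpecies(mass=1000.0, z=1)


@pytest.fixture
def bisinusoidal():
    return AsymmetricWaveform.bisinusoidal(ratio=2.0)
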