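import numpy as np
import pytest

from nanodose.beam_models import EnergySpectrum, make_kvp_spectrum, make_6mv_spectrum
from nanodose.macro_transport import run_macro_photons, run_macro_protons


def mono_spectrum(energy_kev: float, species: str = "photon") -> EnergySpectrum:
    return EnergySpectrum(np.array([energy_kev - 0.5, energy_kev + 0.5]),
                          np.array([1.0]), species=species)


@pytest.fixture(scope="session")
def kvp_spectrum():
    return make_kvp_spectrum()


@pytest.fixture(scope="session")
def mv6_spectrum():
    return make_6mv_spectrum()


@pytest.fixture(scope="session")
def kvp_macro(kvp_spectrum):
    """Shared 140 kVp stage-1 run (moderate statistics)."""
    return run_macro_photons(kvp_spectrum, 12000, 101)


@pytest.fixture(scope="session")
def kvp_at_70mm(kvp_macro):
    return kvp_macro.spectrum_at(70.0)


@pytest.fixture(scope="session")
def mv6_macro(mv6_spectrum):
    return run_macro_photons(mv6_spectrum, 10000, 101)


@pytest.fixture(scope="session")
def mv6_at_70mm(mv6_macro):
    return mv6_macro.spectrum_at(70.0)


@pytest.fixture(scope="session")
def proton_macro():
    """Shared 95 MeV proton stage-1 run (1e4 histories, 1 mm depth bins)."""
    return run_macro_protons(95.0, 10000, 101)
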