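import numpy as np
import pytest
from hypothesis import settings

import batradar as br

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def system() -> br.RadarSystem:
    """The study radar: 12 kW, 9410 MHz, 31.6 dBi, 0.07 us pulse."""
    return br.furuno_far2117()


@pytest.fixture(scope="session")
def sphere_rcs_m2(system) -> float:
    """Mie backscatter RCS of the 1 cm conducting calibration sphere."""
    return br.mie_pec_rcs(0.005, system.wavelength_m).sigma_m2


@pytest.fixture(scope="session")
def pmin(system, sphere_rcs_m2) -> br.PowerLevel:
    """Minimum detectable signal power from the 550 m sphere calibration."""
    return br.pmin_from_range(system, 550.0, sphere_rcs_m2)


@pytest.fixture(scope="session")
def calibrated(system, pmin) -> br.RadarSystem:
    return system.calibrated(pmin)


@pytest.fixture(scope="session")
def pattern() -> br.AntennaPattern:
    """Default Gaussian main lobe: 31.6 dBi peak, -3 dB at +/-10 deg."""
    return br.gaussian_pattern()


@pytest.fixture(scope="session")
def isotropic_pattern(system) -> br.AntennaPattern:
    """Flat pattern at peak gain (for closed-form boundary oracles)."""
    el = np.arange(-90.0, 90.5, 1.0)
    g = np.full_like(el, system.peak_gain)
    return br.AntennaPattern(elevations_deg=el, gains_linear=g, peak_gain=system.peak_gain)


@pytest.fixture(scope="session")
def csf() -> br.CsfGeometry:
    """The study fence: 2.2 m high, 6 m radius, 2 m antenna."""
    return br.study_csf()
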