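import numpy as np
import pytest

from chromoswitch import (
    default_photophysics,
    get_preset,
    make_calibrated_spectra,
    pss_curve,
)


@pytest.fixture(scope="session")
def spectra():
    """Calibrated synthetic E/Z spectra (anchors 360/410/440 nm)."""
    return make_calibrated_spectra()


@pytest.fixture(scope="session")
def phot():
    return default_photophysics()


@pytest.fixture(scope="session")
def trpc4_azpico():
    return get_preset("trpc4_azpico")


@pytest.fixture(scope="session")
def affinity_ref():
    return get_preset("ideal_affinity_reference")


@pytest.fixture(scope="session")
def default_pss(spectra, phot):
    """PSS curve on the full spectrum grid under the default flux."""
    return pss_curve(spectra, phot)


@pytest.fixture(scope="session")
def flat_eps_z_spectra():
    """Spectra where Z does not absorb at all (phi = 1 everywhere lit)."""
    from chromoswitch import IsomerSpectrumPair

    wl = np.arange(300.0, 551.0, 1.0)
    return IsomerSpectrumPair(
        wavelengths=wl, eps_E=np.full_like(wl, 5000.0), eps_Z=np.zeros_like(wl)
    )
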