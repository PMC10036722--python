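import warnings

import pytest

from rvspect import phantom as ph
from rvspect.lv import segment_lv
from rvspect.rv import segment_rv

warnings.filterwarnings("ignore", message="LV ellipsoid fit did not converge")


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, blur-free default phantom (hard-edged shells)."""
    spec = ph.PhantomSpec(psf_fwhm_mm=0, apply_poisson=False, apply_butterworth=False)
    vol, truth = ph.generate_phantom(spec)
    return vol, truth


@pytest.fixture(scope="session")
def clean_lv(clean_phantom):
    vol, _ = clean_phantom
    return segment_lv(vol)


@pytest.fixture(scope="session")
def clean_rv(clean_phantom, clean_lv):
    vol, _ = clean_phantom
    return segment_rv(vol, clean_lv, fallback_to_init=True)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with the full degradation chain (seed 7)."""
    vol, truth = ph.generate_phantom(ph.PhantomSpec(seed=7))
    return vol, truth


@pytest.fixture(scope="session")
def full_ellipsoid_phantom():
    """Untruncated LV ellipsoid shell: exact-recovery fixture for the LV fit."""
    spec = ph.PhantomSpec(
        psf_fwhm_mm=0,
        apply_poisson=False,
        apply_butterworth=False,
        lv_basal_fraction=1.0,
    )
    return ph.generate_phantom(spec), spec

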