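import numpy as np
import pytest

from rsacap import RSAKinetics, default_scenario, integrate_rsa_kinetics


@pytest.fixture(scope="session")
def table1_kinetics() -> RSAKinetics:
    """Reference parameter set (CNF-like: k_a=1e-5 cm/s, a=6e4 nm^2)."""
    return RSAKinetics(k_a=1.0e-5, a_nm2=6.0e4, m=5.26e-7, c=1.0e5)


@pytest.fixture(scope="session")
def reference_trace(table1_kinetics):
    """Noiseless Gamma(t) over 1 h at 10 s sampling."""
    t = np.arange(0.0, 3601.0, 10.0)
    return t, integrate_rsa_kinetics(table1_kinetics, t)


@pytest.fixture
def small_image_scenario():
    """Compact imaging scenario used by the image-analysis tests."""
    return default_scenario(seed=0, image_shape=(768, 1024), nm_per_px=4.0)
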