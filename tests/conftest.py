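import numpy as np
import pytest

import poremech as pm


@pytest.fixture(scope="session")
def flat_frame():
    return pm.make_flat_membrane(100, {"POPC": 1.0}, box_xy=8.0, d_hc=2.8, seed=1)


@pytest.fixture(scope="session")
def wire_frame():
    return pm.make_water_wire(100, {"POPC": 1.0}, box_xy=8.0, d_hc=2.8, seed=1,
                              wire_radius=0.15)


@pytest.fixture(scope="session")
def pore_frame():
    return pm.make_pore_membrane(100, {"POPC": 1.0}, box_xy=8.0, d_hc=2.8, seed=1,
                                 pore_radius=0.8)


@pytest.fixture(scope="session")
def golgi_like_pmf():
    """Noiseless profile with the published Golgi-scale energetics."""
    return pm.make_synthetic_pmf(pm.SyntheticPMFSpec(gamma_true=40.0, dG_nuc_true=90.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
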