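"""Shared synthetic-scan fixtures.

All fixtures are generated programmatically and seeded; the session scope
keeps the expensive simulations and fits to one evaluation each.
"""

import numpy as np
import pytest

from pxst.model import PXSTModel
from pxst.phantoms import siemens_preset


@pytest.fixture(scope="session")
def sim_small():
    """Noiseless geometric Siemens-star scan, 128^2 detector, 9x9 positions."""
    return siemens_preset(n_det=128, scan_shape=(9, 9), distortion_px=3.0, flux=None, seed=1)


@pytest.fixture(scope="session")
def sim_small_noisy():
    """Poisson-noise twin of sim_small at 2000 peak counts/pixel."""
    return siemens_preset(n_det=128, scan_shape=(9, 9), distortion_px=3.0, flux=2000.0, seed=1)


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """Three-iteration reconstruction of the small noiseless scan."""
    model = PXSTModel.from_simulation(sim_small)
    return model.fit(n_iter=3, search_radius=7, reg_schedule=[4, 2, 1])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
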