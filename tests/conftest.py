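import numpy as np
import pytest

from bone4d.core import Calibration
from bone4d.synthetic import PhantomSpec, make_cortex_phantom


@pytest.fixture(scope="session")
def circular_spec():
    """Circular tube matching the closed-form worked geometry
    (outer 0.5 mm, inner 0.3 mm → wall 200 µm)."""
    return PhantomSpec(outer_radii=(500.0, 500.0), inner_radii=(300.0, 300.0),
                       length=160.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def circular_phantom(circular_spec):
    return make_cortex_phantom(circular_spec)


@pytest.fixture(scope="session")
def small_annulus():
    """Smaller annulus (wall 150 µm) used where runtime matters."""
    spec = PhantomSpec(outer_radii=(400.0, 400.0), inner_radii=(250.0, 250.0),
                       length=84.0, noise_sd=0.0, seed=3)
    return spec, make_cortex_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def default_calibration():
    return Calibration()
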