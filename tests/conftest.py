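import numpy as np
import pytest

from pwftomo import CoherenceModel, ImagingGeometry


@pytest.fixture
def geometry32():
    return ImagingGeometry(
        nx=32, ny=32, pitch=650e-9, wavelength=0.124e-9, L1=3e-3, L2=20e-3
    )


@pytest.fixture
def geometry64():
    return ImagingGeometry(
        nx=64, ny=64, pitch=650e-9, wavelength=0.124e-9, L1=3e-3, L2=20e-3
    )


@pytest.fixture
def coherence_model():
    # beamline-calibrated values
    return CoherenceModel(x_coh=3.47e-6, y_coh=4.31e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def phantom64():
    """Bead phantom scaled to fit the 64-pixel (41.6 um) field of view."""
    from pwftomo import Phantom, Sphere

    return Phantom(spheres=(
        Sphere(center=(-7.5e-6, -6e-6, 2.5e-6), radius=4e-6,
               delta=6.0e-6, beta=4.5e-8),
        Sphere(center=(5e-6, 0.5e-6, -4e-6), radius=3e-6,
               delta=6.0e-6, beta=4.5e-8),
    ))
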