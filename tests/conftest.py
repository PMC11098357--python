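import numpy as np
import pytest

from vesselvol.phantoms import PhantomSpec, Tube, generate_phantom


@pytest.fixture(scope="session")
def straight_tube_phantom():
    """Noise- and PSF-free cylinder, radius 3 voxels, isotropic 1 μm."""
    spec = PhantomSpec(
        shape=(20, 20, 40),
        tubes=(Tube(np.array([[9.0, 9.0, 0.0], [9.0, 9.0, 39.0]]), 3.0),),
        spacing=(1.0, 1.0, 1.0),
        psf_sigma=(0.0, 0.0, 0.0),
        noise=None,
        seed=7,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def y_phantom():
    """Noise-free Y bifurcation: one constructed degree-3 junction."""
    fork = np.array([13.0, 31.0, 30.0])
    spec = PhantomSpec(
        shape=(28, 64, 64),
        tubes=(
            Tube(np.array([[13.0, 31.0, 2.0], fork]), 2.5),
            Tube(np.array([fork, [13.0, 13.0, 61.0]]), 2.5),
            Tube(np.array([fork, [13.0, 49.0, 61.0]]), 2.5),
        ),
        spacing=(1.0, 1.0, 1.0),
        psf_sigma=(0.0, 0.0, 0.0),
        noise=None,
        seed=11,
    )
    return spec, generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
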