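import numpy as np
import pytest

from ctaperv.simulate import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_spec():
    # zero noise AND zero blur: every voxel is exactly one scene value
    return PhantomSpec(noise_sd=0.0, blur_fwhm=0.0, texture_hu=0.0)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return generate_phantom(default_spec, seed=7)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
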