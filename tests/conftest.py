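import numpy as np
import pytest

from mfiseg import PhantomSpec, default_scheme, generate_phantom


@pytest.fixture(scope="session")
def scheme12():
    """Default 14-label scheme mapped onto 12 axial slices."""
    return default_scheme(12)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """One noiseless cervical phantom: (dixon, mask, truth)."""
    return generate_phantom(PhantomSpec.cervical(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """One noisy cervical phantom with per-scan jitter."""
    spec = PhantomSpec.cervical(
        noise_sd=2.0, seed=7, fraction_jitter_sd=0.03, radius_jitter_frac=0.10
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
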