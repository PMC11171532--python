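import numpy as np
import pytest

from mammosub.phantom import PhantomSpec, generate_bilateral_case


@pytest.fixture(scope="session")
def phantom_case():
    """A small asymmetric noisy phantom shared across tests."""
    spec = PhantomSpec(
        image_height=128,
        image_width=128,
        breast_area_fraction=0.35,
        density_fraction=0.40,
        deform_magnitude=3.0,
        deform_correlation_length=64.0,
        noise_sd=0.01,
        seed=42,
    )
    return generate_bilateral_case(spec, case_id="fixture")


@pytest.fixture(scope="session")
def symmetric_case():
    """Noiseless, deformation-free phantom: flipped left equals right."""
    spec = PhantomSpec(
        image_height=128,
        image_width=128,
        deform_magnitude=0.0,
        noise_sd=0.0,
        seed=7,
    )
    return generate_bilateral_case(spec, case_id="symmetric")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
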