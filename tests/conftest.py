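import numpy as np
import pytest

from mipradiomics.synthetic_data import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom():
    """A default-sized phantom with known ground truth (non-pCR analogue)."""
    return generate_phantom(PhantomSpec(seed=3, class_effect=2.0), label=0, case_id="fixture")


@pytest.fixture(scope="session")
def small_phantom():
    """A smaller, faster phantom for feature-level tests."""
    return generate_phantom(
        PhantomSpec(image_size=(128, 128), vessel_count=3, seed=5), label=1, case_id="small"
    )
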