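import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small balanced dataset for pipeline tests: 2 subjects, 64 clouds, 64 pts."""
    import gsfan

    return gsfan.generate_dataset(
        n_per_class=1, n_subjects=2, n_points=64, noise_sd=1e-3, seed=99
    )
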