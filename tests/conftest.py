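import numpy as np
import pytest

from copdfusion import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects, balanced, separable with mild noise."""
    spec = sd.CohortSpec(
        n_subjects=60, copd_fraction=0.5, ct_effect=1.0, xray_effect=1.0,
        noise_sd=0.05, seed=42,
    )
    return sd.generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = sd.PhantomSpec(lumen_radius=8, outer_radius=12, pixel_size=1.0, noise_sd=0.0)
    return sd.generate_phantom(spec)
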