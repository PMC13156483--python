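import numpy as np
import pytest

from craniomorph.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def clean_spec():
    """Zero-noise, zero-scatter, zero-asymmetry cohort spec (deterministic geometry)."""
    return CohortSpec(
        landmark_noise_sd=0.0, size_sd=0.0, outline_mode_sd=0.0,
        asymmetry={"control": (0.0, (0.0, 0.0)), "LOF": (0.0, (0.0, 0.0)),
                   "GOF": (0.0, (0.0, 0.0))},
        allometry_slope={"control": 0.0, "LOF": 0.0, "GOF": 0.0},
        seed=1)


@pytest.fixture(scope="session")
def clean_cohort(clean_spec):
    cohort, truth = generate_cohort(clean_spec)
    return cohort, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    spec = CohortSpec(seed=5)
    cohort, truth = generate_cohort(spec)
    return cohort, truth
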