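import numpy as np
import pytest

from fclustfd.simulate import CohortDesign, generate_cohort, generate_coefficient_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(20231117)


@pytest.fixture
def blobs_2d():
    """Two well-separated clouds of 10 units each in coefficient space."""
    C, labels = generate_coefficient_blobs(10, [[0.0] * 5, [10.0] * 5], 0.5, seed=1)
    return C, labels


@pytest.fixture
def noisy_sine(rng):
    """A noisy sine on 40 equally spaced days, with its clean signal."""
    t = np.linspace(0.0, 1.0, 40)
    clean = np.sin(2 * np.pi * t)
    return t, clean + 0.1 * rng.standard_normal(40), clean


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic diary cohort for pipeline-level tests."""
    design = CohortDesign(patients_per_cluster=10, n_days=30, seed=42)
    records, labels, pollen = generate_cohort(design)
    return design, records, labels, pollen
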