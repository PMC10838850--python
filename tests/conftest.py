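import numpy as np
import pytest

from sinusmie import (PhantomSpec, SamplingScheme, generate_phantom_cohort,
                      labels_from_truths)


@pytest.fixture(scope="session")
def small_cohort():
    """Quarter-scale cohort of 24 phantoms shared across tests."""
    spec = PhantomSpec.downscaled(scale=0.25, n_patients=24, seed=11)
    volumes, truths = generate_phantom_cohort(spec)
    return spec, volumes, truths


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    _, _, truths = small_cohort
    return labels_from_truths(truths)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
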