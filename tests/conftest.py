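import numpy as np
import pytest

from rgcdegen import pipeline, synthetic_cohort as sc


@pytest.fixture(scope="session")
def library():
    return sc.make_type_library(seed=0)


@pytest.fixture(scope="session")
def cohort_stimuli():
    return sc.make_cohort_stimuli(seed=0)


@pytest.fixture(scope="session")
def noise_stimuli():
    """Stimulus set including the rasterized shifted dense noise (slow)."""
    return sc.make_cohort_stimuli(seed=0, include_noise=True)


@pytest.fixture(scope="session")
def classifier(library, cohort_stimuli):
    return pipeline.build_classifier(library, cohort_stimuli)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
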