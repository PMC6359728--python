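import numpy as np
import pytest

import spraymsm as sm

#: Fixed seed for all synthetic study fixtures.
FIXTURE_SEED = 0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_vectors() -> dict[str, np.ndarray]:
    """Two well-separated synthetic categories, 200 preprocessed frames each.

    Template distance (crop rows vs bare soil) is an order of magnitude above
    the appearance noise, so the classes are linearly separable after
    preprocessing.
    """
    a, b = sm.default_two_class_params(separable=True, seed=FIXTURE_SEED)
    return {
        "spray": sm.vectorize_stream(sm.generate_scene_sequence(a)),
        "non_spray": sm.vectorize_stream(sm.generate_scene_sequence(b)),
    }


@pytest.fixture(scope="session")
def chance_vectors() -> dict[str, np.ndarray]:
    """Zero-separation fixture: both categories share one template.

    Temporal correlation is switched off here so per-image decisions are
    approximately independent and comparable to a binomial reference.
    """
    a, b = sm.default_two_class_params(separable=False, seed=FIXTURE_SEED, temporal_corr=0.0)
    return {
        "spray": sm.vectorize_stream(sm.generate_scene_sequence(a)),
        "non_spray": sm.vectorize_stream(sm.generate_scene_sequence(b)),
    }
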