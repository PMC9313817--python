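import numpy as np
import pytest

from muscleseg import PhantomParams, generate_phantom, to_model_input, window_level


@pytest.fixture(scope="session")
def small_cohort():
    """20 phantoms at 64 px / 6 mm, shared across tests."""
    params = PhantomParams(cohort_size=20, image_side=64, spacing_mm=6.0)
    return generate_phantom(params, seed=12345)


@pytest.fixture(scope="session")
def small_inputs(small_cohort):
    return [
        to_model_input(window_level(ct), provenance=ct.slice_id)
        for ct, _, _ in small_cohort
    ]


def random_mask(rng, shape=(16, 16), p=0.4, spacing=(1.0, 1.0)):
    from muscleseg import BinaryMask

    labels = (rng.random(shape) < p).astype(np.uint8)
    return BinaryMask(labels=labels, spacing=spacing, role="ground_truth")
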