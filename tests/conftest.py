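import numpy as np
import pytest

import airtrap as at


@pytest.fixture(scope="session")
def small_phantom():
    """A modest paired phantom with 30% trapped lung, shared across tests."""
    spec = at.PhantomSpec(
        grid_shape=(64, 64, 48), spacing=(2.5, 2.5, 2.5), trapped_fraction=0.3, seed=11
    )
    insp, exp, truth = at.generate_phantom(spec)
    return spec, insp, exp, truth


@pytest.fixture(scope="session")
def segmented_phantom(small_phantom):
    spec, insp, exp, truth = small_phantom
    mask = at.segment_lung(exp)
    return spec, insp, exp, truth, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
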