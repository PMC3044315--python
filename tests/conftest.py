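import numpy as np
import pytest

import micasel as mcs


@pytest.fixture(scope="session")
def small_profile() -> mcs.ExpressionProfile:
    """A modest separable two-class profile shared by many tests."""
    return mcs.generate_two_class_profile(
        mcs.SyntheticSpec(p_per_class=15, n=256, effect_size=3.0, seed=3))


@pytest.fixture(scope="session")
def fitted(small_profile):
    """(model, meta) fit of the shared profile with default-ish parameters."""
    return mcs.fit_mica(small_profile, level=4, tau=3, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
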