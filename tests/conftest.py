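import numpy as np
import pytest

from paircause.causality import PairedSample
from paircause.synthetic import default_profile, make_pair, model_from_profile


@pytest.fixture(scope="session")
def mbdi_profile():
    """Young Finns sleep-problems / mBDI moment profile."""
    return default_profile("young_finns_mbdi")


@pytest.fixture(scope="session")
def mbdi_model(mbdi_profile):
    """Ground-truth generating model implied by the profile."""
    return model_from_profile(mbdi_profile)


@pytest.fixture(scope="session")
def causal_pair(mbdi_profile):
    """One strongly-causal synthetic pair at the study's n."""
    sample, _ = make_pair(mbdi_profile, seed=42)
    return sample


@pytest.fixture(scope="session")
def small_causal_pair(mbdi_model):
    """Reduced-n strongly-causal pair for expensive statistics."""
    from dataclasses import replace
    from paircause.simulation import draw_pair

    model = replace(mbdi_model, n=600)
    x, e, y = draw_pair(model, seed=7)
    return PairedSample(x, y, "cause", "effect")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
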