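import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated SIP experiment under the default study conditions."""
    from sipseq import sipsim

    community = sipsim.default_community(seed=1)
    dataset = sipsim.simulate_experiment(community, sipsim.SIPDesign(seed=1))
    return community, dataset


@pytest.fixture(scope="session")
def marker_panel():
    from sipseq import sdimo

    return sdimo.synthetic_panel(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
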