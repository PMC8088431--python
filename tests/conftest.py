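import pytest
from hypothesis import HealthCheck, settings

import hrescan as hs
from hrescan.matrix import ILLUSTRATIVE_CONSENSUS

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def illustrative():
    """The bundled illustrative 33-bp HRE matrix."""
    return hs.illustrative_matrix()


@pytest.fixture(scope="session")
def consensus_matrix():
    """A consensus-only matrix (pseudocount 0): plants exact consensus windows."""
    return hs.build_psfm([ILLUSTRATIVE_CONSENSUS] * 2, pseudocount=0.0)
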