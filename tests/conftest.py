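import numpy as np
import pytest

from ipsckit import calibrate_scheme, default_scheme
from ipsckit import params as P


@pytest.fixture(scope="session")
def fast_scheme():
    """Gating scheme calibrated to the mean fast eIPSC decay component."""
    return calibrate_scheme(default_scheme(), P.FAST_DECAY_TARGET_MS, vary="all")


@pytest.fixture(scope="session")
def slow_scheme(fast_scheme):
    """Fast scheme re-calibrated (unbinding only) to the mean slow component."""
    return calibrate_scheme(fast_scheme, P.SLOW_DECAY_TARGET_MS,
                            vary="binding_unbinding_only")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
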