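import warnings

import numpy as np
import pytest

from cabum.synthdata import SynthConfig, simulate_session

warnings.filterwarnings("ignore", message="input already at 250")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """13-min session with 3 contractions at known times; shared across tests."""
    cfg = SynthConfig(
        duration_s=780.0,
        n_contractions=None,
        event_times_s=(150.0, 420.0, 650.0),
        seed=42,
    )
    return cfg, simulate_session(cfg)
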