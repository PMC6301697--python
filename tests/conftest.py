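import numpy as np
import pytest


@pytest.fixture(scope="session")
def small_scenario_kwargs():
    """Desk-scale network for fast unit tests."""
    return dict(cells_per_lobe=30, duration=96.0, transient=24.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20181210)
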