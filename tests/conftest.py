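import numpy as np
import pytest

from hemovar import (
    PulseShapeSpec,
    TachogramSpec,
    simulate_tachogram,
)


@pytest.fixture(scope="session")
def constant_tachogram():
    """2000 beats at a constant 150 ms pulse interval."""
    return simulate_tachogram(TachogramSpec(base_pi=150.0, duration=300.0))


@pytest.fixture(scope="session")
def lf_tachogram():
    """Pure 0.4 Hz modulation, amplitude 10 ms (band power 50 ms^2)."""
    return simulate_tachogram(
        TachogramSpec(base_pi=150.0, amp_lf=10.0, freq_lf=0.4, duration=300.0)
    )


@pytest.fixture(scope="session")
def default_shape():
    return PulseShapeSpec(sap=180.0, dap=120.0, sampling_rate=2000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
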