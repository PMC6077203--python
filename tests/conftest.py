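import numpy as np
import pytest

from gabashift import PRESETS, AcquisitionSpec, simulate_channel_trace, simulate_patch_protocol


@pytest.fixture(scope="session")
def fig1_patch():
    """Two-channel patch (19 & 7.3 pS, Erev -11 mV) at V = +80 mV, 5 s."""
    acq = AcquisitionSpec(noise_sd=0.15, duration=5.0, V=80.0)
    return simulate_channel_trace(PRESETS["fig1-example"], acq, seed=7)


@pytest.fixture(scope="session")
def fig1_protocol():
    """The same patch recorded at five potentials, 10 s each."""
    acq = AcquisitionSpec(noise_sd=0.15, duration=10.0)
    return simulate_patch_protocol(
        PRESETS["fig1-example"], acq, [20, 35, 50, 65, 80], seed=7
    )


@pytest.fixture(scope="session")
def single_channel_patch():
    """One 19 pS channel at +80 mV with low noise, 5 s."""
    acq = AcquisitionSpec(noise_sd=0.04, duration=5.0, V=80.0)
    return simulate_channel_trace([PRESETS["fig1-example"][0]], acq, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20180730)
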