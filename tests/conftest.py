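import numpy as np
import pytest

from emgonset import (
    FIVE_BURST_SPECS,
    add_noise_for_snr,
    condition_signal,
    simulate_clean_emg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def five_burst_trial_10db():
    """Conditioned five-burst trial at 10 dB (the multi-burst detection protocol)."""
    clean = simulate_clean_emg(12.0, 2000.0, FIVE_BURST_SPECS, seed=3)
    noisy = add_noise_for_snr(clean, 10.0, seed=4)
    return condition_signal(noisy)


@pytest.fixture(scope="session")
def single_burst_clean():
    """Clean 4-s trial with one burst from 1 to 3 s (the comparison protocol)."""
    from emgonset import BurstSpec

    return simulate_clean_emg(4.0, 2000.0, [BurstSpec(1.0, 3.0)], seed=1)
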