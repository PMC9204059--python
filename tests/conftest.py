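import numpy as np
import pytest

from wingbeatid import (CleaningConfig, SimConfig, default_profiles,
                        reference_clean_record, simulate_dataset)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def cleaning_config():
    return CleaningConfig()


@pytest.fixture(scope="session")
def reference_record():
    """The deterministic clean fixture: f0 = 220 Hz, five overtones."""
    return reference_clean_record()


@pytest.fixture(scope="session")
def small_dataset():
    """40 labeled records (2 species x 2 populations x 10) plus manifest."""
    config = SimConfig(n_records=10, rng_seed=123)
    return simulate_dataset(config, default_profiles())


def pure_tone_record(freq, fs=8000, n=5000, amp=1.0):
    from wingbeatid import WingbeatRecord
    t = np.arange(n) / fs
    return WingbeatRecord(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)
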