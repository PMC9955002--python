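import numpy as np
import pytest

from seiztype import (
    DEFAULT_ARCHETYPES,
    DatasetSpec,
    SignalSegment,
    simulate_channel,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Nine synthetic channels (3 per class) at the reference 400 Hz / 4 s."""
    spec = DatasetSpec({"TCSZ": 3, "CPSZ": 3, "EGSZ": 3}, seed=11)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def one_channel_per_class():
    return {
        label: simulate_channel(DEFAULT_ARCHETYPES[label], seed=101)
        for label in ("TCSZ", "CPSZ", "EGSZ")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def white_noise_segment(rng):
    return SignalSegment(rng.standard_normal(1600), 400.0, "noise")
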