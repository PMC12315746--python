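import logging

import numpy as np
import pandas as pd
import pytest

from prestim.config import SimConfig, default_channels
from prestim.synthgen import EpochSet

logging.getLogger("prestim").setLevel(logging.ERROR)
logging.getLogger("py.warnings").setLevel(logging.ERROR)


@pytest.fixture
def tiny_config() -> SimConfig:
    """Two subjects per group, one sequence, four channels."""
    return SimConfig(
        n_subjects_per_group=2, n_sequences=1,
        channels=default_channels(2, 2), n_frontal=2, seed=11,
    )


def make_epochs(samples: np.ndarray, fs: float = 500.0,
                t0: float = -750.0) -> EpochSet:
    """Wrap a raw [epoch, channel, time] array as a single-repetition set."""
    n_ep, n_ch, n_t = samples.shape
    times = t0 + np.arange(n_t) * 1000.0 / fs
    meta = pd.DataFrame({
        "subject": ["s1"] * n_ep, "group": ["young"] * n_ep,
        "sequence": [1] * n_ep, "repetition": [1] * n_ep,
        "stimulus": list(range(1, n_ep + 1)), "fixation": [1] * n_ep,
    })
    channels = [f"c{i}" for i in range(n_ch)]
    return EpochSet(samples, times, channels, meta, fs)


@pytest.fixture
def epoch_factory():
    return make_epochs
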