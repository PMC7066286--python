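import numpy as np
import pandas as pd
import pytest

from p3tacs import SimConfig
from p3tacs.preprocess import EpochSet


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A short session: enough trials for averages, quick to synthesize."""
    return SimConfig(n_trials=60, seed=7)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    from p3tacs import simulate_session

    return simulate_session(small_cfg, seed=7)


def make_epochs(data: np.ndarray, fs: float = 1000.0, t0_ms: float = -3000.0,
                stimulus_type: str = "target", channels=None) -> EpochSet:
    """EpochSet straight from an array (trials x channels x time)."""
    n, n_ch, n_t = data.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch - 1)] + ["Pz"]
    times = t0_ms + np.arange(n_t) * 1000.0 / fs
    meta = pd.DataFrame(
        {
            "stimulus_type": [stimulus_type] * n,
            "rejected": False,
            "rejection_reason": "",
        }
    )
    return EpochSet(
        data=data,
        times_ms=times,
        channel_labels=list(channels),
        metadata=meta,
        sampling_rate_hz=fs,
    )
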