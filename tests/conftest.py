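import numpy as np
import pandas as pd
import pytest

import multisync as ms
from multisync.preprocess import EpochSet


@pytest.fixture(scope="session")
def spec():
    return ms.StimulusSpec()


@pytest.fixture(scope="session")
def melody_sim(spec):
    """One simulated melody-condition block, band-passed, reused by the
    PLV/preprocess tests (16 trials, 16 channels, 512 Hz)."""
    rng = np.random.default_rng(0)
    block = ms.build_block(rng, condition="target+melody", n_patterns=8)
    block.trials = block.trials[:16]
    params = ms.desk_scale_params(seed=11)
    res = ms.simulate_block(block, params, spec)
    eeg = ms.bandpass_and_reref(res.eeg)
    return eeg, res.trials


def make_epochs(data: np.ndarray, fs: float = 512.0,
                window_kind: str = "cycle") -> EpochSet:
    """Wrap a raw (epochs x channels x samples) array as an EpochSet."""
    n = data.shape[0]
    meta = pd.DataFrame({"trial_index": np.zeros(n, dtype=int)})
    labels = [f"c{i}" for i in range(data.shape[1])]
    return EpochSet(data, fs, window_kind, meta, labels)
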