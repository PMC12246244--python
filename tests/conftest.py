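import numpy as np
import pytest

import eegmultiverse as emv


@pytest.fixture(scope="session")
def small_config():
    return emv.default_config(n_participants=2, n_trials=(40, 40), seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    recs, gt = emv.generate_study(small_config)
    return recs, gt


@pytest.fixture(scope="session")
def prepared(small_study):
    recs, _ = small_study
    return [emv.prepare_recording(r) for r in recs]


@pytest.fixture(scope="session")
def small_epochs(prepared, small_config):
    return emv.epoch(prepared[0], small_config.epoch_window)


def make_epochs(data, sfreq=100.0, t0=-0.2, labels=None, names=None):
    """Tiny EpochSet builder for algebraic unit tests."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_times = data.shape
    if labels is None:
        labels = np.arange(n_trials) % 2
    if names is None:
        scalp = ["Cz", "Pz", "Fz", "C3", "C4", "P3", "P4", "Fp2", "P9", "P10"]
        names = scalp[:n_ch]
    times = t0 + np.arange(n_times) / sfreq
    return emv.EpochSet(data=data, labels=np.asarray(labels), times=times,
                        channel_names=list(names), sfreq=sfreq)
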