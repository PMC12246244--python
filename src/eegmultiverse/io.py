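"""HDF5 epoch container and tabular exports.

The on-disk epoch container stores the trials x channels x time array with
labels, times, channel names and provenance as HDF5 datasets/attributes, so
externally epoched data can be imported into the pipeline and intermediate
results can be checkpointed.
"""

from __future__ import annotations

import h5py
import numpy as np

from .containers import EpochSet

__all__ = ["save_epochs", "load_epochs"]


def save_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("labels", data=epochs.labels)
        fh.create_dataset("times", data=epochs.times)
        fh.create_dataset("kept_trial_index", data=epochs.kept_trial_index)
        fh.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype()))
        fh.attrs["sfreq"] = epochs.sfreq
        fh.attrs["participant_id"] = epochs.participant_id


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        return EpochSet(
            data=fh["data"][()],
            labels=fh["labels"][()],
            times=fh["times"][()],
            kept_trial_index=fh["kept_trial_index"][()],
            channel_names=[s.decode() if isinstance(s, bytes) else str(s)
                           for s in fh["channel_names"][()]],
            sfreq=float(fh.attrs["sfreq"]),
            participant_id=int(fh.attrs["participant_id"]),
        )
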