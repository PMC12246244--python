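"""Core data containers shared across the pipeline.

The unit of raw simulation is a :class:`ContinuousRecording` (one participant's
continuous multichannel signal plus an event table).  The unit of preprocessing
and decoding is an :class:`EpochSet` (trials x channels x time).  Channels are
identified by 10-20 style names; periocular (EOG) channels are bookkeeping
channels that are filtered like scalp channels but excluded from referencing,
ICA component estimation and decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Schematic 2-D head layout (x: left->right, y: posterior->anterior), unit head
# radius.  28 scalp positions approximating the 10-20 system, including the
# near-mastoid pair P9/P10, plus three periocular source channels.
SCALP_LAYOUT: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.41, 0.55), "Fz": (0.0, 0.55),
    "F4": (0.41, 0.55), "F8": (0.81, 0.59),
    "FC3": (-0.45, 0.28), "FCz": (0.0, 0.28), "FC4": (0.45, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP3": (-0.45, -0.28), "CPz": (0.0, -0.28), "CP4": (0.45, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.41, -0.55), "Pz": (0.0, -0.55),
    "P4": (0.41, -0.55), "P8": (0.81, -0.59),
    "P9": (-0.95, -0.75), "P10": (0.95, -0.75),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.95), "O2": (0.31, -0.95),
}

EOG_SOURCE_LAYOUT: dict[str, tuple[float, float]] = {
    "HEOG_left": (-1.05, 1.0),
    "HEOG_right": (1.05, 1.0),
    "VEOG_lower": (0.35, 1.12),
}

#: Channel names treated as non-scalp bookkeeping channels.
NON_SCALP = frozenset(EOG_SOURCE_LAYOUT) | {"HEOG", "VEOG"}

LAYOUT_POS: dict[str, tuple[float, float]] = {**SCALP_LAYOUT, **EOG_SOURCE_LAYOUT}


def channel_positions(channel_names: list[str]) -> np.ndarray:
    """Return (n_channels, 2) schematic positions for known channel names."""
    pos = np.zeros((len(channel_names), 2))
    for i, name in enumerate(channel_names):
        if name in LAYOUT_POS:
            pos[i] = LAYOUT_POS[name]
    return pos


class ChannelError(ValueError):
    """A required channel is missing from a recording or epoch set."""


class PathInvalidError(RuntimeError):
    """A forking path cannot be completed for a participant.

    Raised e.g. when trial rejection leaves fewer trials per class than the
    downstream cross-validation fold count; the caller records the path as
    invalid for that participant rather than aborting the multiverse run.
    """


@dataclass
class ContinuousRecording:
    """Continuous multichannel signal (microvolts) with an event table.

    ``events`` is an integer array of shape (n_events, 2): sample index of the
    event onset and the binary condition label.
    """

    data: np.ndarray            # (n_channels, n_samples), microvolts
    sfreq: float
    channel_names: list[str]
    events: np.ndarray          # (n_events, 2) int: sample, label in {0, 1}
    participant_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if self.events.size:
            if self.events.ndim != 2 or self.events.shape[1] != 2:
                raise ValueError("events must be (n_events, 2)")
            samples = self.events[:, 0]
            if np.any(np.diff(samples) <= 0):
                raise ValueError("event samples must be strictly increasing")
            if samples.min() < 0 or samples.max() >= self.data.shape[1]:
                raise ValueError("event samples out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.channel_names)
                         if n not in NON_SCALP], dtype=int)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelError(f"channel {name!r} not present") from None

    def copy(self) -> "ContinuousRecording":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names),
                       events=self.events.copy())


@dataclass
class EpochSet:
    """Epoched trials (trials x channels x time, microvolts) with labels.

    ``times`` is in seconds relative to the event onset, uniformly sampled at
    1/sfreq and inclusive of both window endpoints.  ``kept_trial_index``
    tracks provenance of each row through trial rejection (indices into the
    original event table).
    """

    data: np.ndarray            # (n_trials, n_channels, n_times)
    labels: np.ndarray          # (n_trials,) in {0, 1}
    times: np.ndarray           # (n_times,) seconds
    channel_names: list[str]
    sfreq: float
    participant_id: int = 0
    kept_trial_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if self.times.shape[0] != self.data.shape[2]:
            raise ValueError("times length must match data time axis")
        if self.kept_trial_index is None:
            self.kept_trial_index = np.arange(self.data.shape[0])
        else:
            self.kept_trial_index = np.asarray(self.kept_trial_index, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.channel_names)
                         if n not in NON_SCALP], dtype=int)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ChannelError(f"channel {name!r} not present") from None

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), labels=self.labels.copy(),
                       times=self.times.copy(),
                       channel_names=list(self.channel_names),
                       kept_trial_index=self.kept_trial_index.copy())
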