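"""Shared in-memory containers for recordings, task events and epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Task timing constants (ms): cue -> imperative stimulus, pair -> pair,
#: and on-screen stimulus duration.
CUE_TO_SECOND_MS = 1000
INTER_PAIR_MS = 3000
STIMULUS_DURATION_MS = 100

PAIR_TYPES = ("aa", "ap", "pp", "ph")


@dataclass(frozen=True)
class Trial:
    """One cue/imperative stimulus pair of the cued GO/NOGO task."""

    pair_type: str                 # one of PAIR_TYPES
    cue_onset_ms: float
    second_onset_ms: float
    stimulus_duration_ms: float = STIMULUS_DURATION_MS
    response_time_ms: Optional[float] = None   # relative to second stimulus


@dataclass
class EventList:
    """Ordered trials of one task session."""

    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def validate_timing(self) -> None:
        for i, t in enumerate(self.trials):
            if t.pair_type not in PAIR_TYPES:
                raise ValueError(f"unknown pair type {t.pair_type!r}")
            if t.second_onset_ms - t.cue_onset_ms != CUE_TO_SECOND_MS:
                raise ValueError(f"trial {i}: cue->second interval != {CUE_TO_SECOND_MS} ms")
            if t.stimulus_duration_ms != STIMULUS_DURATION_MS:
                raise ValueError(f"trial {i}: stimulus duration != {STIMULUS_DURATION_MS} ms")
            if i > 0:
                prev = self.trials[i - 1]
                if t.cue_onset_ms - prev.second_onset_ms != INTER_PAIR_MS:
                    raise ValueError(f"trial {i}: inter-pair interval != {INTER_PAIR_MS} ms")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(len(self.trials)),
                "pair_type": [t.pair_type for t in self.trials],
                "cue_onset_ms": [t.cue_onset_ms for t in self.trials],
                "second_onset_ms": [t.second_onset_ms for t in self.trials],
                "stimulus_duration_ms": [t.stimulus_duration_ms for t in self.trials],
                "response_time_ms": [t.response_time_ms for t in self.trials],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventList":
        trials = []
        for row in df.itertuples():
            rt = row.response_time_ms
            trials.append(
                Trial(
                    pair_type=row.pair_type,
                    cue_onset_ms=float(row.cue_onset_ms),
                    second_onset_ms=float(row.second_onset_ms),
                    stimulus_duration_ms=float(row.stimulus_duration_ms),
                    response_time_ms=None if rt is None or (isinstance(rt, float) and np.isnan(rt)) else float(rt),
                )
            )
        return cls(trials=trials)


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is (n_channels, n_samples).  ``reference`` tracks the montage
    reference state ('linked_ears' as recorded, 'weighted_average' after
    re-referencing).  ``button`` is an optional response channel (same
    length as the EEG) carrying unit pulses at button presses.
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float
    reference: str = "linked_ears"
    events: Optional[EventList] = None
    subject_id: str = ""
    condition: str = ""
    button: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy_with(self, **kwargs) -> "EEGRecording":
        out = replace(self, **kwargs)
        return out


# Artifact-rule flags an epoch can carry.
FLAG_ABS = "abs"
FLAG_SLOW = "slow"
FLAG_FAST = "fast"


@dataclass
class EpochSet:
    """Consecutive fixed-length epochs with per-epoch artifact flags.

    ``epochs`` is (n_epochs, n_channels, n_samples); ``flags`` holds, per
    epoch, the set of artifact rules that fired (empty set == clean).
    """

    epochs: np.ndarray
    channel_labels: tuple[str, ...]
    sampling_rate: float
    flags: list[set]
    condition_labels: list[str]
    start_samples: np.ndarray       # epoch start index in the source recording
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        n = self.epochs.shape[0]
        if not (len(self.flags) == len(self.condition_labels) == len(self.start_samples) == n):
            raise ValueError("per-epoch metadata length mismatch")
        allowed = {FLAG_ABS, FLAG_SLOW, FLAG_FAST}
        for fl in self.flags:
            if not set(fl) <= allowed:
                raise ValueError(f"unknown artifact flag in {fl}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def clean_mask(self) -> np.ndarray:
        return np.array([len(f) == 0 for f in self.flags], dtype=bool)

    @property
    def n_clean(self) -> int:
        return int(self.clean_mask.sum())

    def select(self, mask: np.ndarray) -> "EpochSet":
        idx = np.where(mask)[0]
        return EpochSet(
            epochs=self.epochs[idx],
            channel_labels=self.channel_labels,
            sampling_rate=self.sampling_rate,
            flags=[set(self.flags[i]) for i in idx],
            condition_labels=[self.condition_labels[i] for i in idx],
            start_samples=self.start_samples[idx],
            subject_id=self.subject_id,
            condition=self.condition,
        )


class QualityGateError(RuntimeError):
    """A subject/condition failed a data-quality requirement."""
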