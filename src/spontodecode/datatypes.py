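"""Core in-memory containers: the continuous recording and the event table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: stimulus classes the decoder knows about
CLASSES = ("face", "house")
#: label used for inter-stimulus-interval (null) points
NULL_LABEL = "isi"


@dataclass
class ContinuousRecording:
    """Multichannel potential stream sampled at 1000 Hz.

    ``potentials`` is a (n_samples, n_channels) array in µV; at 1 kHz one
    sample is one millisecond, and the time index is 0-based.
    ``bad_channel_mask`` marks channels excluded from re-referencing and
    decoding (True = bad).
    """

    potentials: np.ndarray
    sampling_rate_hz: float = 1000.0
    channel_labels: list[str] = field(default_factory=list)
    bad_channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials)
        if self.potentials.ndim != 2:
            raise ValueError("potentials must be a (n_samples, n_channels) matrix")
        n_ch = self.potentials.shape[1]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n_ch)]
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length does not match channel count")
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros(n_ch, dtype=bool)
        else:
            self.bad_channel_mask = np.asarray(self.bad_channel_mask, dtype=bool)
            if self.bad_channel_mask.shape != (n_ch,):
                raise ValueError("bad_channel_mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[1]

    @property
    def good_channels(self) -> np.ndarray:
        return np.flatnonzero(~self.bad_channel_mask)

    def copy_with(self, potentials: np.ndarray) -> "ContinuousRecording":
        return ContinuousRecording(
            potentials=potentials,
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=list(self.channel_labels),
            bad_channel_mask=self.bad_channel_mask.copy(),
        )


@dataclass
class EventTable:
    """Stimulus onsets (ms / sample index at 1 kHz) with class labels and run ids."""

    onset_ms: np.ndarray
    labels: np.ndarray
    run: np.ndarray

    def __post_init__(self) -> None:
        self.onset_ms = np.asarray(self.onset_ms, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.run = np.asarray(self.run, dtype=np.int64)
        if not (len(self.onset_ms) == len(self.labels) == len(self.run)):
            raise ValueError("onset_ms, labels and run must have equal length")
        if np.any(self.onset_ms < 0):
            raise ValueError("negative stimulus onset")
        bad = set(np.unique(self.labels)) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown stimulus classes: {sorted(bad)}")
        if len(self.onset_ms) > 1 and np.any(np.diff(self.onset_ms) < 0):
            logger.warning("event table not sorted by onset; sorting")
            order = np.argsort(self.onset_ms, kind="stable")
            self.onset_ms = self.onset_ms[order]
            self.labels = self.labels[order]
            self.run = self.run[order]

    def __len__(self) -> int:
        return len(self.onset_ms)

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run)

    def subset(self, mask: np.ndarray) -> "EventTable":
        return EventTable(self.onset_ms[mask], self.labels[mask], self.run[mask])

    def for_runs(self, runs) -> "EventTable":
        runs = np.atleast_1d(runs)
        return self.subset(np.isin(self.run, runs))

    def for_class(self, label: str) -> "EventTable":
        return self.subset(self.labels == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_ms": self.onset_ms, "class": self.labels, "run": self.run}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        return cls(
            df["onset_ms"].to_numpy(),
            df["class"].to_numpy(),
            df["run"].to_numpy(),
        )
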