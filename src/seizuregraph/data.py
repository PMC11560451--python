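"""Core data containers: continuous recordings and windowed segment sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """One subject's continuous multichannel EEG.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` array, amplitude in nominal microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Bipolar-derivation labels, one per signal row (e.g. ``"FP1-F7"``).
    seizure_intervals
        Half-open ``[onset_s, offset_s)`` intervals, in seconds from record
        start, marking ictal stretches. Everything else is interictal.
    patient_id
        Subject label used for split bookkeeping.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    patient_id: str = "P00"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.duration_s
        for onset, offset in self.seizure_intervals:
            if not (0.0 <= onset < offset <= dur + 1e-9):
                raise ValueError(
                    f"seizure interval ({onset}, {offset}) outside record "
                    f"of duration {dur:.3f} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    def label_track(self) -> np.ndarray:
        """Per-sample binary labels: 1 inside a seizure interval, else 0."""
        labels = np.zeros(self.n_samples, dtype=np.int8)
        for onset, offset in self.seizure_intervals:
            i0 = int(round(onset * self.fs))
            i1 = int(round(offset * self.fs))
            labels[i0:i1] = 1
        return labels


@dataclass
class SegmentSet:
    """Fixed-length windowed segments with binary labels and subject ids.

    ``segments`` has shape ``(n_segments, n_channels, window_samples)``;
    ``labels`` is 1 for ictal windows, 0 for interictal.
    """

    segments: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    fs: float
    window_s: float

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.patient_ids = np.asarray(self.patient_ids)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_segments, channels, samples)")
        n = self.segments.shape[0]
        if self.labels.shape != (n,) or self.patient_ids.shape != (n,):
            raise ValueError("labels and patient_ids must match segment count")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def window_samples(self) -> int:
        return self.segments.shape[2]

    def subset(self, indices: np.ndarray) -> "SegmentSet":
        idx = np.asarray(indices, dtype=np.intp)
        return SegmentSet(
            self.segments[idx],
            self.labels[idx],
            self.patient_ids[idx],
            self.fs,
            self.window_s,
        )

    def class_counts(self) -> tuple[int, int]:
        """(interictal, ictal) segment counts."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    @staticmethod
    def concatenate(sets: list["SegmentSet"]) -> "SegmentSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        fs, w = sets[0].fs, sets[0].window_s
        if any(s.fs != fs or s.window_s != w for s in sets):
            raise ValueError("segment sets disagree on fs or window length")
        return SegmentSet(
            np.concatenate([s.segments for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.patient_ids for s in sets]),
            fs,
            w,
        )
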