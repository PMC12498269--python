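"""Core in-memory containers shared across the pipeline.

All containers are thin dataclasses around numpy arrays with just enough
validation to catch wiring mistakes early.  Times are seconds, frame shifts
and windows are milliseconds, sample rates are Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "FrameSequence",
    "BaselineStats",
    "LabelSequence",
    "SegmentList",
    "GroundTruth",
    "NON_SPEECH",
    "SPEECH",
    "BINARY_CLASSES",
]

#: Binary class convention used everywhere: 0 = non-speech, 1 = speech.
NON_SPEECH = 0
SPEECH = 1
BINARY_CLASSES = {NON_SPEECH: "non-speech", SPEECH: "speech"}


@dataclass
class RawRecording:
    """Multichannel raw neural recording (samples x channels).

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, n_channels)``.
    sample_rate
        Sampling rate in Hz (1000 for the reference configuration).
    channel_ids
        One label per channel (e.g. ``"ch007"``).
    grid_of_channel
        Electrode-grid index of each channel; common average referencing is
        applied per grid.
    bad_channels
        Labels of channels excluded from all processing.
    """

    samples: np.ndarray
    sample_rate: float
    channel_ids: list[str]
    grid_of_channel: np.ndarray
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_channels)")
        n_ch = self.samples.shape[1]
        if len(self.channel_ids) != n_ch:
            raise ValueError("channel_ids length must match channel count")
        self.grid_of_channel = np.asarray(self.grid_of_channel, dtype=np.int64)
        if self.grid_of_channel.shape != (n_ch,):
            raise ValueError("grid_of_channel must have one entry per channel")
        unknown = set(self.bad_channels) - set(self.channel_ids)
        if unknown:
            raise ValueError(f"bad_channels not in channel_ids: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class FrameSequence:
    """Feature frames (T x D), 50 ms windows advancing by 10 ms by default."""

    values: np.ndarray
    frame_shift_ms: float = 10.0
    window_ms: float = 50.0
    start_time: float = 0.0
    channel_ids: list[str] = field(default_factory=list)
    normalized: bool = False
    stack_lags: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (T, D)")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def frame_time(self, index: int) -> float:
        """Start time (s) of the window underlying frame ``index``."""
        return self.start_time + index * self.frame_shift_ms / 1000.0

    def with_values(self, values: np.ndarray, **changes) -> "FrameSequence":
        return replace(self, values=np.asarray(values, dtype=np.float64), **changes)


@dataclass
class BaselineStats:
    """Per-feature mean/sd fitted on a baseline (syllable-task) segment."""

    mean: np.ndarray
    sd: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have identical shapes")
        if np.any(self.sd <= 0):
            raise ValueError("sd must be strictly positive (floored upstream)")


@dataclass
class LabelSequence:
    """Per-frame integer labels at the feature frame rate."""

    labels: np.ndarray
    frame_shift_ms: float = 10.0
    start_time: float = 0.0
    classes: dict[int, str] = field(default_factory=lambda: dict(BINARY_CLASSES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def is_binary(self) -> bool:
        return bool(np.all((self.labels == 0) | (self.labels == 1)))

    def with_labels(self, labels: np.ndarray, classes: dict[int, str] | None = None) -> "LabelSequence":
        return LabelSequence(
            labels=np.asarray(labels, dtype=np.int64),
            frame_shift_ms=self.frame_shift_ms,
            start_time=self.start_time,
            classes=dict(classes) if classes is not None else dict(self.classes),
        )


@dataclass
class SegmentList:
    """Run-length view of a label sequence: half-open (start, end, label) runs."""

    segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, _label in self.segments:
            if start != prev_end:
                raise ValueError("segments must tile the sequence without gaps/overlaps")
            if end <= start:
                raise ValueError("segments must be non-empty, half-open intervals")
            prev_end = end

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_frames(self) -> int:
        return self.segments[-1][1] if self.segments else 0


@dataclass
class GroundTruth:
    """Reference speech timing for a synthetic session.

    ``vad`` holds binary 10 ms frame labels; ``trials`` is a table with columns
    ``trial_index, word_id, cue_onset, speech_onset, speech_offset`` (seconds,
    snapped to the 10 ms frame grid so labels and table agree exactly).
    """

    vad: LabelSequence
    trials: pd.DataFrame
    baseline_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        required = {"trial_index", "word_id", "cue_onset", "speech_onset", "speech_offset"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")

    @property
    def mean_speech_duration(self) -> float:
        d = self.trials["speech_offset"] - self.trials["speech_onset"]
        return float(d.mean())
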