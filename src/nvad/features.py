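"""High-gamma feature extraction from raw multichannel recordings.

The pipeline is: per-grid common average referencing, causal 4th-order
Butterworth band-pass 70-170 Hz, causal 4th-order Butterworth band-stop
118-122 Hz (first line-noise harmonic), then log power over 50 ms windows
advancing by 10 ms, z-scored against a per-day baseline segment.

Every filter runs strictly forward (single causal pass, no filtfilt): a frame
only ever depends on samples at or before the end of its window, which is
what makes the streaming path reproduce the offline path frame for frame.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal

from .types import BaselineStats, FrameSequence, RawRecording

__all__ = [
    "LOG_EPS",
    "SD_FLOOR",
    "DEFAULT_STACK_LAGS",
    "hg_filter_cascade",
    "preprocess_raw",
    "extract_hg_power",
    "fit_baseline_stats",
    "apply_zscore",
    "stack_context",
    "frame_count",
    "log_window_power",
]

logger = logging.getLogger(__name__)

#: numeric floor inside the log so silent windows stay finite
LOG_EPS = 1e-10
#: floor for baseline standard deviations (constant features)
SD_FLOOR = 1e-6
#: non-overlapping 50 ms context steps back to -300 ms, in 10 ms frames
DEFAULT_STACK_LAGS = (0, 5, 10, 15, 20, 25, 30)

HG_BAND = (70.0, 170.0)
NOTCH_BAND = (118.0, 122.0)
WINDOW_MS = 50.0
SHIFT_MS = 10.0


def hg_filter_cascade(sample_rate: float) -> np.ndarray:
    """Second-order sections of the band-pass + band-stop cascade."""
    if sample_rate < 2 * HG_BAND[1]:
        raise ValueError(f"sample_rate {sample_rate} too low for {HG_BAND[1]} Hz band edge")
    sos_bp = signal.butter(4, HG_BAND, btype="bandpass", fs=sample_rate, output="sos")
    sos_notch = signal.butter(4, NOTCH_BAND, btype="bandstop", fs=sample_rate, output="sos")
    return np.vstack([sos_bp, sos_notch])


def preprocess_raw(rec: RawRecording, selected_channels: list[str]) -> RawRecording:
    """Drop bad channels, apply per-grid CAR, then keep ``selected_channels``.

    The common average of each grid is computed over that grid's retained
    (non-bad) channels at every sample and subtracted from each of them.
    ``selected_channels`` are returned in the given order.
    """
    bad = set(rec.bad_channels)
    for ch in selected_channels:
        if ch in bad:
            raise ValueError(f"selected channel {ch!r} is marked bad")
        if ch not in rec.channel_ids:
            raise ValueError(f"unknown channel {ch!r}")

    keep = [i for i, ch in enumerate(rec.channel_ids) if ch not in bad]
    data = rec.samples[:, keep].copy()
    ids = [rec.channel_ids[i] for i in keep]
    grids = rec.grid_of_channel[keep]

    for g in np.unique(grids):
        cols = np.flatnonzero(grids == g)
        data[:, cols] -= data[:, cols].mean(axis=1, keepdims=True)

    order = [ids.index(ch) for ch in selected_channels]
    return RawRecording(
        samples=data[:, order],
        sample_rate=rec.sample_rate,
        channel_ids=list(selected_channels),
        grid_of_channel=grids[order],
        bad_channels=[],
    )


def frame_count(n_samples: int, sample_rate: float,
                window_ms: float = WINDOW_MS, shift_ms: float = SHIFT_MS) -> int:
    """Number of complete windows: floor((n - window) / shift) + 1, or 0."""
    win = int(round(window_ms * sample_rate / 1000.0))
    shift = int(round(shift_ms * sample_rate / 1000.0))
    if n_samples < win:
        return 0
    return (n_samples - win) // shift + 1


def log_window_power(window: np.ndarray) -> np.ndarray:
    """log(mean(x^2) + eps) per channel for one (win_samples, C) window.

    Shared by the offline extractor and the streaming framer node so both
    paths perform bit-identical arithmetic on identical samples.
    """
    return np.log(np.mean(window * window, axis=0) + LOG_EPS)


def extract_hg_power(rec: RawRecording) -> FrameSequence:
    """Causal band-pass/notch filtering followed by framed log power."""
    sos = hg_filter_cascade(rec.sample_rate)
    filtered = signal.sosfilt(sos, rec.samples, axis=0)
    win = int(round(WINDOW_MS * rec.sample_rate / 1000.0))
    shift = int(round(SHIFT_MS * rec.sample_rate / 1000.0))
    n_frames = frame_count(rec.n_samples, rec.sample_rate)
    values = np.empty((n_frames, rec.n_channels), dtype=np.float64)
    for t in range(n_frames):
        values[t] = log_window_power(filtered[t * shift:t * shift + win])
    return FrameSequence(
        values=values,
        frame_shift_ms=SHIFT_MS,
        window_ms=WINDOW_MS,
        start_time=0.0,
        channel_ids=list(rec.channel_ids),
        normalized=False,
    )


def fit_baseline_stats(baseline_frames: FrameSequence, source: str = "") -> BaselineStats:
    """Per-feature mean and population sd of a baseline segment.

    Zero-variance features get their sd floored at :data:`SD_FLOOR` (with a
    logged warning) so z-scoring maps them to exactly zero.
    """
    if len(baseline_frames) < 2:
        raise ValueError("baseline needs at least 2 frames")
    mean = baseline_frames.values.mean(axis=0)
    sd = baseline_frames.values.std(axis=0)  # population convention (ddof=0)
    degenerate = sd < SD_FLOOR
    if np.any(degenerate):
        logger.warning("flooring sd for %d constant feature(s)", int(degenerate.sum()))
        sd = np.where(degenerate, SD_FLOOR, sd)
    return BaselineStats(mean=mean, sd=sd, source=source)


def apply_zscore(frames: FrameSequence, stats: BaselineStats) -> FrameSequence:
    """(x - mean) / sd per feature, using baseline statistics."""
    if stats.mean.shape[0] != frames.n_features:
        raise ValueError("baseline statistics do not match feature dimension")
    values = (frames.values - stats.mean) / stats.sd
    return frames.with_values(values, normalized=True)


def stack_context(frames: FrameSequence, lags_frames: tuple[int, ...] = DEFAULT_STACK_LAGS) -> FrameSequence:
    """Concatenate each frame with lagged past frames (zero-filled at start).

    Row ``t`` becomes ``(x[t - lag] for lag in lags_frames)`` concatenated; a
    lag reaching before the sequence start contributes zeros, which equals the
    baseline mean in z-scored space.
    """
    lags = tuple(int(l) for l in lags_frames)
    if not lags or lags[0] != 0 or any(l < 0 for l in lags) or list(lags) != sorted(lags):
        raise ValueError("lags must be sorted, non-negative, and start with 0")
    if len(lags) == 1:
        return replace(frames, stack_lags=(0,))
    x = frames.values
    T, C = x.shape
    out = np.zeros((T, C * len(lags)), dtype=np.float64)
    for k, lag in enumerate(lags):
        if lag < T:
            out[lag:, k * C:(k + 1) * C] = x[:T - lag]
    return frames.with_values(out, stack_lags=lags)
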