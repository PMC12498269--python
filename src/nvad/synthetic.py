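"""Synthetic sessions with known speech timing for end-to-end testing.

Two levels of fidelity:

* :func:`generate_feature_session` draws feature frames directly from two
  Gaussian Markov random fields (speech / non-speech), the generative model
  the clustering stage assumes.  Used to test cluster recovery in isolation.
* :func:`generate_raw_session` emulates a cued-word recording day at the raw
  signal level: 1 kHz multichannel pink noise with a shared per-grid common
  mode, a 120 Hz line-noise harmonic, day-specific multiplicative gain, a
  prepended baseline (syllable-task surrogate) segment, and band-limited
  70-170 Hz amplitude bursts on a subset of channels during speech.  A
  white-noise burst audio track at 48 kHz provides the acoustic surrogate
  for the reference VAD.

Each trial presents a cue for 2 s followed by a 3 s inter-trial interval;
speech onsets shortly after the cue and lasts ~1.2 s on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .features import SHIFT_MS, WINDOW_MS, frame_count
from .types import BINARY_CLASSES, FrameSequence, GroundTruth, LabelSequence, RawRecording

__all__ = [
    "SessionConfig",
    "sample_block_toeplitz_precision",
    "sample_disjoint_precision_pair",
    "trial_schedule",
    "generate_feature_session",
    "generate_raw_session",
]


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording day.

    Defaults mirror the cued single-word reading protocol: 2 s cue, 3 s
    inter-trial interval, 50-word vocabulary with each word repeated twice
    (100 trials), ~1.2 s mean speech duration, two 64-channel grids sampled
    at 1 kHz, and a syllable-task baseline at the start of the day.
    """

    n_channels: int = 64
    n_grids: int = 2
    sample_rate: float = 1000.0
    n_trials: int = 100
    cue_duration: float = 2.0
    iti_duration: float = 3.0
    speech_duration_mean: float = 1.2
    speech_duration_sd: float = 0.25
    speech_duration_min: float = 0.3
    speech_onset_delay: float = 0.2
    speech_onset_jitter: float = 0.4
    speech_channel_set: tuple[int, ...] | None = None
    speech_gain: float = 1.5
    day_gain_sd: float = 0.1
    line_noise_hz: float = 120.0
    line_noise_amplitude: float = 2.0
    baseline_duration: float = 30.0
    vocabulary_size: int = 50
    audio_rate: float = 48000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speech_channel_set is None:
            # a minority of each grid carries speech modulation: per-grid CAR
            # removes the common mode, so concentrating all speech channels in
            # one grid would leak comparable (inverted) modulation onto the
            # rest of that grid and blur the spatial structure
            grid_size = max(1, self.n_channels // self.n_grids)
            per_grid = max(1, grid_size // 8)
            chans = []
            for g in range(self.n_grids):
                start = g * grid_size
                chans.extend(range(start, min(start + per_grid, self.n_channels)))
            self.speech_channel_set = tuple(chans)
        if len(self.speech_channel_set) == 0:
            raise ValueError("speech_channel_set must be non-empty")
        if self.cue_duration + self.iti_duration <= self.speech_duration_mean:
            raise ValueError("trial must be longer than the mean speech duration")
        if min(self.cue_duration, self.iti_duration, self.speech_duration_mean,
               self.baseline_duration) <= 0:
            raise ValueError("all durations must be positive")
        bad = [c for c in self.speech_channel_set if not 0 <= c < self.n_channels]
        if bad:
            raise ValueError(f"speech channels out of range: {bad}")

    @property
    def trial_duration(self) -> float:
        return self.cue_duration + self.iti_duration

    @property
    def session_duration(self) -> float:
        return self.baseline_duration + self.n_trials * self.trial_duration


def sample_block_toeplitz_precision(n_channels: int, n_layers: int, density: float,
                                    strength: float, seed: int,
                                    max_retries: int = 20) -> np.ndarray:
    """Draw a random sparse, symmetric, PD, block-Toeplitz precision matrix.

    Off-diagonal entries of each C x C lag block are nonzero with probability
    ``density`` and magnitude ~``strength``; the block at lag ``m`` is reused
    at every position ``(i, i+m)`` of the (w*C) x (w*C) matrix.  Diagonal
    loading is increased until the matrix is positive definite.
    """
    if n_channels < 2 or n_layers < 1:
        raise ValueError("need n_channels >= 2 and n_layers >= 1")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    C, w = n_channels, n_layers

    blocks = []
    for m in range(w):
        mask = rng.random((C, C)) < density
        vals = rng.uniform(0.5, 1.0, (C, C)) * rng.choice([-1.0, 1.0], (C, C)) * strength
        B = np.where(mask, vals, 0.0)
        if m == 0:
            B = np.triu(B, 1)
            B = B + B.T
        blocks.append(B)

    theta = np.zeros((w * C, w * C))
    for i in range(w):
        for j in range(w):
            m = j - i
            theta[i * C:(i + 1) * C, j * C:(j + 1) * C] = blocks[m] if m >= 0 else blocks[-m].T
    theta = (theta + theta.T) / 2.0

    load = 1.0
    for _ in range(max_retries):
        candidate = theta + load * np.eye(w * C)
        min_eig = float(np.linalg.eigvalsh(candidate)[0])
        if min_eig > 1e-6:
            return candidate
        load = (load - min_eig) * 1.5
    raise RuntimeError("failed to reach positive definiteness after retries")


def sample_disjoint_precision_pair(n_channels: int, n_layers: int, density: float,
                                   strength: float, seed: int
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Two block-Toeplitz precisions whose off-diagonal supports are disjoint.

    Used to pose well-separated covariance-clustering problems: each cluster
    has conditional dependencies on its own set of channel pairs, so the two
    Gaussians differ strongly while sharing the same (zero) mean.
    """
    if n_channels < 2 or n_layers < 1:
        raise ValueError("need n_channels >= 2 and n_layers >= 1")
    rng = np.random.default_rng(seed)
    C, w = n_channels, n_layers

    def build(block_masks):
        theta = np.zeros((w * C, w * C))
        blocks = []
        for m in range(w):
            vals = rng.uniform(0.5, 1.0, (C, C)) * rng.choice([-1.0, 1.0], (C, C)) * strength
            B = np.where(block_masks[m], vals, 0.0)
            if m == 0:
                B = np.triu(B, 1)
                B = B + B.T
            blocks.append(B)
        for i in range(w):
            for j in range(w):
                m = j - i
                theta[i * C:(i + 1) * C, j * C:(j + 1) * C] = blocks[m] if m >= 0 else blocks[-m].T
        theta = (theta + theta.T) / 2.0
        load = 1.0
        for _ in range(20):
            candidate = theta + load * np.eye(w * C)
            min_eig = float(np.linalg.eigvalsh(candidate)[0])
            if min_eig > 1e-6:
                return candidate
            load = (load - min_eig) * 1.5
        raise RuntimeError("failed to reach positive definiteness after retries")

    masks_a, masks_b = [], []
    for m in range(w):
        r = rng.random((C, C))
        masks_a.append(r < density)
        masks_b.append((r >= density) & (r < 2 * density))
    return build(masks_a), build(masks_b)


def trial_schedule(n_trials: int, speech_frames: int = 120,
                   nonspeech_frames: int = 380) -> list[tuple[int, int]]:
    """Alternating (n_frames, label) plan: each trial is speech then silence."""
    plan: list[tuple[int, int]] = []
    for _ in range(n_trials):
        plan.append((speech_frames, 1))
        plan.append((nonspeech_frames, 0))
    return plan


def generate_feature_session(schedule: list[tuple[int, int]],
                             speech_mrf: tuple[np.ndarray, np.ndarray],
                             nonspeech_mrf: tuple[np.ndarray, np.ndarray],
                             seed: int) -> tuple[FrameSequence, GroundTruth]:
    """Sample frames from per-class Gaussian MRFs along a segment plan.

    ``speech_mrf`` / ``nonspeech_mrf`` are ``(mean, precision)`` pairs of equal
    dimension.  Frames in each segment are drawn i.i.d. from the corresponding
    Gaussian; the returned labels are exactly the sampled schedule.
    """
    mu1, theta1 = speech_mrf
    mu0, theta0 = nonspeech_mrf
    mu1, mu0 = np.asarray(mu1, float), np.asarray(mu0, float)
    if mu1.shape != mu0.shape or theta1.shape != theta0.shape or theta1.shape[0] != mu1.shape[0]:
        raise ValueError("speech and non-speech MRFs must share dimensions")

    rng = np.random.default_rng(seed)
    chol = {
        1: np.linalg.cholesky(np.linalg.inv(theta1)),
        0: np.linalg.cholesky(np.linalg.inv(theta0)),
    }
    means = {1: mu1, 0: mu0}
    chunks, labels = [], []
    trial_rows = []
    t0 = 0
    trial_idx = 0
    for n_frames, label in schedule:
        z = rng.standard_normal((n_frames, mu1.shape[0]))
        chunks.append(means[label] + z @ chol[label].T)
        labels.append(np.full(n_frames, label, dtype=np.int64))
        if label == 1:
            shift_s = SHIFT_MS / 1000.0
            trial_rows.append({
                "trial_index": trial_idx,
                "word_id": trial_idx % 50,
                "cue_onset": t0 * shift_s,
                "speech_onset": t0 * shift_s,
                "speech_offset": (t0 + n_frames) * shift_s,
            })
            trial_idx += 1
        t0 += n_frames

    frames = FrameSequence(
        values=np.vstack(chunks) if chunks else np.empty((0, mu1.shape[0])),
        channel_ids=[f"f{i:03d}" for i in range(mu1.shape[0])],
        normalized=True,
    )
    truth = GroundTruth(
        vad=LabelSequence(np.concatenate(labels) if labels else np.empty(0, np.int64),
                          classes=dict(BINARY_CLASSES)),
        trials=pd.DataFrame(trial_rows,
                            columns=["trial_index", "word_id", "cue_onset",
                                     "speech_onset", "speech_offset"]),
    )
    return frames, truth


def _pink_noise(rng: np.random.Generator, n: int, n_cols: int) -> np.ndarray:
    """1/f-amplitude noise columns, unit variance."""
    white = rng.standard_normal((n, n_cols))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale[:, None], n=n, axis=0)
    pink /= pink.std(axis=0, keepdims=True)
    return pink


def _snap(t: float, shift_s: float) -> float:
    return round(t / shift_s) * shift_s


def generate_raw_session(config: SessionConfig) -> tuple[RawRecording, GroundTruth, np.ndarray]:
    """Emulate one recording day at the raw-signal level.

    Returns the raw recording, ground-truth speech timing (10 ms frame labels
    plus trial table, both snapped to the frame grid), and a 48 kHz audio
    surrogate with noise bursts aligned to the speech intervals.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    n = int(round(cfg.session_duration * fs))
    C = cfg.n_channels
    shift_s = SHIFT_MS / 1000.0

    grid_of_channel = np.arange(C) * cfg.n_grids // C
    channel_ids = [f"ch{i:03d}" for i in range(C)]

    # background: per-channel pink noise + shared per-grid common mode
    data = _pink_noise(rng, n, C)
    for g in range(cfg.n_grids):
        common = _pink_noise(rng, n, 1)[:, 0]
        data[:, grid_of_channel == g] += 0.5 * common[:, None]

    # line-noise harmonic with per-channel phase
    t_axis = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, C)
    data += cfg.line_noise_amplitude * np.sin(
        2 * np.pi * cfg.line_noise_hz * t_axis[:, None] + phases[None, :])

    # trial timing, snapped to the 10 ms frame grid
    trial_rows = []
    for k in range(cfg.n_trials):
        cue_onset = cfg.baseline_duration + k * cfg.trial_duration
        onset = cue_onset + cfg.speech_onset_delay + rng.uniform(0, cfg.speech_onset_jitter)
        dur = rng.normal(cfg.speech_duration_mean, cfg.speech_duration_sd)
        dur = float(np.clip(dur, cfg.speech_duration_min,
                            cfg.trial_duration - cfg.speech_onset_delay - cfg.speech_onset_jitter - 0.1))
        onset = _snap(onset, shift_s)
        offset = _snap(onset + dur, shift_s)
        trial_rows.append({
            "trial_index": k,
            "word_id": k % cfg.vocabulary_size,
            "cue_onset": _snap(cue_onset, shift_s),
            "speech_onset": onset,
            "speech_offset": offset,
        })
    trials = pd.DataFrame(trial_rows)

    # speech bursts: one band-limited latent envelope mixed into the speech
    # channels with per-channel loadings -> distinct spatial covariance
    if cfg.speech_gain > 0:
        sos = signal.butter(4, (70.0, 170.0), btype="bandpass", fs=fs, output="sos")
        loadings = rng.uniform(0.8, 1.5, len(cfg.speech_channel_set))
        band_std = data[:, list(cfg.speech_channel_set)].std()
        for row in trial_rows:
            i0 = int(round(row["speech_onset"] * fs))
            i1 = int(round(row["speech_offset"] * fs))
            seg = i1 - i0
            carrier = signal.sosfilt(sos, rng.standard_normal(seg))
            carrier /= max(carrier.std(), 1e-12)
            envelope = signal.windows.tukey(seg, alpha=0.25)
            burst = cfg.speech_gain * band_std * envelope * carrier
            data[i0:i1, list(cfg.speech_channel_set)] += burst[:, None] * loadings[None, :]

    # day-specific multiplicative gain drift (shared baseline + trials)
    gains = np.exp(rng.normal(0.0, cfg.day_gain_sd, C))
    data *= gains[None, :]

    # frame-level ground truth: frame t covers [t*shift, t*shift + window)
    T = frame_count(n, fs, WINDOW_MS, SHIFT_MS)
    vad = np.zeros(T, dtype=np.int64)
    for row in trial_rows:
        f0 = int(round(row["speech_onset"] / shift_s))
        f1 = int(round(row["speech_offset"] / shift_s))
        vad[f0:min(f1, T)] = 1

    # audio surrogate: white-noise bursts over a low noise floor
    n_audio = int(round(cfg.session_duration * cfg.audio_rate))
    audio = 1e-3 * rng.standard_normal(n_audio)
    for row in trial_rows:
        a0 = int(round(row["speech_onset"] * cfg.audio_rate))
        a1 = int(round(row["speech_offset"] * cfg.audio_rate))
        envelope = signal.windows.tukey(a1 - a0, alpha=0.25)
        audio[a0:a1] += 0.3 * envelope * rng.standard_normal(a1 - a0)

    rec = RawRecording(samples=data, sample_rate=fs, channel_ids=channel_ids,
                       grid_of_channel=grid_of_channel, bad_channels=[])
    truth = GroundTruth(vad=LabelSequence(vad, classes=dict(BINARY_CLASSES)), trials=trials,
                        baseline_interval=(0.0, cfg.baseline_duration))
    return rec, truth, audio
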