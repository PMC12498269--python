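"""Evaluation: alignment error, detection metrics, cross-validation harness,
hyperparameter grid search, channel contributions, and the acoustic
reference VAD surrogate.

The headline metric is the alignment error: 10 ms times the Levenshtein
distance between the predicted and reference binary frame-label strings, so
substitutions, insertions and deletions each cost one 10 ms frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import signal

from .classifiers import TrainingConfig, predict_offline, train_classifier
from .features import apply_zscore, fit_baseline_stats
from .labeling import infer_class_map, relabel
from .ticc import TICCHyperparams, TICCModel, fit_ticc
from .types import FrameSequence, GroundTruth, LabelSequence

__all__ = [
    "alignment_error",
    "frame_rates",
    "TrialMetrics",
    "trial_metrics",
    "DaySession",
    "EvalReport",
    "run_lodo_cv",
    "grid_search_hyperparams",
    "ContributionMap",
    "channel_contributions",
    "reference_vad",
]

logger = logging.getLogger(__name__)


def alignment_error(pred: LabelSequence, target: LabelSequence) -> float:
    """10 ms x Levenshtein distance between two binary label sequences."""
    if not pred.is_binary or not target.is_binary:
        raise ValueError("alignment error is defined on binary label sequences")
    if pred.frame_shift_ms != target.frame_shift_ms:
        raise ValueError("frame shifts differ")
    p = pred.labels.astype(np.uint8).tobytes()
    t = target.labels.astype(np.uint8).tobytes()
    if not p or not t:
        distance = max(len(p), len(t))
    else:
        distance = edlib.align(p, t, mode="NW", task="distance")["editDistance"]
    return 10.0 * distance


def frame_rates(pred: LabelSequence, target: LabelSequence) -> tuple[float | None, float | None]:
    """(speech detection probability, false alarm probability).

    Detection = TP / (TP + FN) over reference speech frames; false alarm =
    FP / (FP + TN) over reference non-speech frames.  A probability whose
    denominator is empty is returned as ``None`` rather than zero.
    """
    if len(pred) != len(target):
        raise ValueError("length mismatch")
    p, t = pred.labels, target.labels
    n_speech = int(np.count_nonzero(t == 1))
    n_silence = int(np.count_nonzero(t == 0))
    detection = float(np.count_nonzero(p[t == 1] == 1)) / n_speech if n_speech else None
    false_alarm = float(np.count_nonzero(p[t == 0] == 1)) / n_silence if n_silence else None
    return detection, false_alarm


@dataclass
class TrialMetrics:
    per_trial_error_ms: list[float]
    n_not_detected: int
    majority_detection_rate: float
    n_error_above_mean_duration: int


def _time_to_frame(t: float, seq: LabelSequence) -> int:
    return int(round((t - seq.start_time) / (seq.frame_shift_ms / 1000.0)))


def trial_metrics(pred: LabelSequence, truth: GroundTruth) -> TrialMetrics:
    """Per-trial alignment errors plus detection bookkeeping.

    Each trial is scored on the window [cue onset, next cue onset), so both
    missed speech and spurious detections in the inter-trial interval count.
    A trial is detected-majority iff strictly more than half of its reference
    speech frames are predicted speech; not detected iff none of them are.
    Errors above the mean speech duration are counted but kept in the list.
    """
    trials = truth.trials.sort_values("cue_onset").reset_index(drop=True)
    if len(trials) == 0:
        raise ValueError("empty trial table")
    T = len(pred)
    mean_dur_ms = truth.mean_speech_duration * 1000.0
    errors, n_not_detected, n_majority, n_above = [], 0, 0, 0
    for i, row in trials.iterrows():
        w0 = _time_to_frame(row["cue_onset"], pred)
        w1 = _time_to_frame(trials.loc[i + 1, "cue_onset"], pred) if i + 1 < len(trials) else T
        w0, w1 = max(w0, 0), min(w1, T)
        err = alignment_error(pred.with_labels(pred.labels[w0:w1]),
                              truth.vad.with_labels(truth.vad.labels[w0:w1]))
        errors.append(err)
        if err > mean_dur_ms:
            n_above += 1
        s0 = max(_time_to_frame(row["speech_onset"], pred), 0)
        s1 = min(_time_to_frame(row["speech_offset"], pred), T)
        speech_pred = pred.labels[s0:s1]
        if speech_pred.size and np.count_nonzero(speech_pred) == 0:
            n_not_detected += 1
        if speech_pred.size and np.count_nonzero(speech_pred) > 0.5 * speech_pred.size:
            n_majority += 1
    return TrialMetrics(per_trial_error_ms=errors,
                        n_not_detected=n_not_detected,
                        majority_detection_rate=n_majority / len(trials),
                        n_error_above_mean_duration=n_above)


# ---------------------------------------------------------------------------
# leave-one-day-out cross-validation

@dataclass
class DaySession:
    """One recording day prepared for evaluation: unnormalized feature
    frames, the day's baseline segment, ground truth, and reference labels
    (from the acoustic surrogate, or ground truth when no audio exists)."""

    day_id: str
    frames: FrameSequence
    baseline_frames: FrameSequence
    truth: GroundTruth
    reference: LabelSequence


@dataclass
class EvalReport:
    per_trial_error_ms: list[float]
    median_error_ms: float
    q1_error_ms: float
    q3_error_ms: float
    detection_probability: float | None
    false_alarm_probability: float | None
    majority_detection_rate: float
    n_not_detected: int
    n_error_above_mean_duration: int
    per_fold: list[dict] = field(default_factory=list)


def _day_training_labels(day: DaySession, z: FrameSequence, label_source: str,
                         hyper: TICCHyperparams, seed: int) -> LabelSequence:
    if label_source == "reference":
        return day.reference
    if label_source == "shuffled":
        import zlib
        rng = np.random.default_rng(seed + zlib.crc32(day.day_id.encode()) % 100000)
        return day.reference.with_labels(rng.permutation(day.reference.labels))
    if label_source == "ticc":
        model, clusters = fit_ticc(z, hyper)
        return relabel(clusters, infer_class_map(clusters))
    raise ValueError(f"unknown label_source {label_source!r}")


def run_lodo_cv(days: list[DaySession], cfg: TrainingConfig,
                label_source: str = "ticc",
                hyper: TICCHyperparams | None = None,
                dev_day: str | None = None,
                seed: int = 0) -> EvalReport:
    """Leave-one-day-out cross-validation.

    Each fold holds out one day for testing and the next remaining day for
    validation; classifiers train on the rest.  Every day is z-scored
    against its own baseline segment.  ``label_source`` selects the training
    labels: ``"ticc"`` (unsupervised clustering per day), ``"reference"``
    (acoustic reference labels), or ``"shuffled"`` (permuted reference
    labels, a chance-level control).  The designated development day is
    excluded throughout.  Evaluation is always against ground truth.
    """
    hyper = hyper or TICCHyperparams()
    used = [d for d in days if d.day_id != dev_day]
    if len(used) < 3:
        raise ValueError("leave-one-day-out needs at least 3 days")

    z_frames, train_labels = {}, {}
    for day in used:
        stats = fit_baseline_stats(day.baseline_frames, source=day.day_id)
        z_frames[day.day_id] = apply_zscore(day.frames, stats)
        train_labels[day.day_id] = _day_training_labels(
            day, z_frames[day.day_id], label_source, hyper, seed)

    all_errors: list[float] = []
    per_fold = []
    pooled = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    n_trials_total = n_majority = n_not_detected = n_above = 0
    for i, test_day in enumerate(used):
        rest = [d for d in used if d.day_id != test_day.day_id]
        val_day = rest[i % len(rest)]
        train_days = [d for d in rest if d.day_id != val_day.day_id]

        train = [(z_frames[d.day_id], train_labels[d.day_id]) for d in train_days]
        val = [(z_frames[val_day.day_id], train_labels[val_day.day_id])]
        model = train_classifier(train, val, cfg)
        pred = predict_offline(model, z_frames[test_day.day_id])

        tm = trial_metrics(pred, test_day.truth)
        det, fa = frame_rates(pred, test_day.truth.vad)
        t = test_day.truth.vad.labels
        p = pred.labels[: len(t)]
        pooled["tp"] += int(np.count_nonzero((p == 1) & (t[: len(p)] == 1)))
        pooled["fn"] += int(np.count_nonzero((p == 0) & (t[: len(p)] == 1)))
        pooled["fp"] += int(np.count_nonzero((p == 1) & (t[: len(p)] == 0)))
        pooled["tn"] += int(np.count_nonzero((p == 0) & (t[: len(p)] == 0)))
        n_trials = len(test_day.truth.trials)
        n_trials_total += n_trials
        n_majority += round(tm.majority_detection_rate * n_trials)
        n_not_detected += tm.n_not_detected
        n_above += tm.n_error_above_mean_duration
        all_errors.extend(tm.per_trial_error_ms)
        per_fold.append({
            "test_day": test_day.day_id,
            "val_day": val_day.day_id,
            "median_error_ms": float(np.median(tm.per_trial_error_ms)),
            "detection_probability": det,
            "false_alarm_probability": fa,
            "majority_detection_rate": tm.majority_detection_rate,
            "n_not_detected": tm.n_not_detected,
        })
        logger.info("fold %s: median error %.0f ms", test_day.day_id,
                    per_fold[-1]["median_error_ms"])

    q1, med, q3 = np.percentile(all_errors, [25, 50, 75])
    denom_d = pooled["tp"] + pooled["fn"]
    denom_f = pooled["fp"] + pooled["tn"]
    return EvalReport(
        per_trial_error_ms=all_errors,
        median_error_ms=float(med), q1_error_ms=float(q1), q3_error_ms=float(q3),
        detection_probability=pooled["tp"] / denom_d if denom_d else None,
        false_alarm_probability=pooled["fp"] / denom_f if denom_f else None,
        majority_detection_rate=n_majority / n_trials_total,
        n_not_detected=n_not_detected,
        n_error_above_mean_duration=n_above,
        per_fold=per_fold,
    )


def grid_search_hyperparams(frames: FrameSequence, truth: GroundTruth,
                            beta_grid: list[float], lam_grid: list[float],
                            base: TICCHyperparams | None = None
                            ) -> tuple[float, float, pd.DataFrame]:
    """Pick (beta, lam) minimizing the median per-trial alignment error of
    the relabeled clustering on a calibration session."""
    if not beta_grid or not lam_grid:
        raise ValueError("grids must be nonempty")
    base = base or TICCHyperparams()
    rows = []
    for beta in beta_grid:
        for lam in lam_grid:
            hyper = TICCHyperparams(K=base.K, beta=beta, lam=lam,
                                    n_layers=base.n_layers,
                                    dilation_frames=base.dilation_frames,
                                    max_iter=base.max_iter, seed=base.seed)
            try:
                _, clusters = fit_ticc(frames, hyper)
                binary = relabel(clusters, infer_class_map(clusters))
                med = float(np.median(trial_metrics(binary, truth).per_trial_error_ms))
            except (ValueError, RuntimeError) as exc:
                logger.warning("grid point beta=%s lam=%s failed: %s", beta, lam, exc)
                med = np.nan
            rows.append({"beta": beta, "lam": lam, "median_error_ms": med})
    table = pd.DataFrame(rows)
    if table["median_error_ms"].isna().all():
        raise RuntimeError("every grid point failed")
    best = table.loc[table["median_error_ms"].idxmin()]
    return float(best["beta"]), float(best["lam"]), table


# ---------------------------------------------------------------------------
# channel contributions

@dataclass
class ContributionMap:
    """Per-channel absolute precision differences between the speech and
    non-speech MRFs: the same-electrode (diagonal) term and the total
    interdependency (sum over connections to all other electrodes), both
    from the lag-0 block; cross-lag blocks are summarized separately."""

    per_channel_contribution: np.ndarray
    per_channel_interdependency: np.ndarray
    cross_lag_difference: float


def channel_contributions(model: TICCModel) -> ContributionMap:
    if model.K != 2:
        raise ValueError("channel contributions are defined for K = 2")
    w = model.hyper.n_layers
    D = model.clusters[0].dim
    C = D // w
    diff = np.abs(model.clusters[0].precision - model.clusters[1].precision)
    lag0 = diff[:C, :C]
    contribution = np.diag(lag0).copy()
    interdependency = lag0.sum(axis=1) - np.diag(lag0)
    cross = float(diff.sum() - np.sum([diff[a * C:(a + 1) * C, a * C:(a + 1) * C].sum()
                                       for a in range(w)]))
    return ContributionMap(per_channel_contribution=contribution,
                           per_channel_interdependency=interdependency,
                           cross_lag_difference=cross)


# ---------------------------------------------------------------------------
# acoustic reference VAD surrogate

#: energy-based reference VAD settings
VAD_RATE = 16000
VAD_SMOOTH_FRAMES = 5
VAD_NOISE_PERCENTILE = 20.0
VAD_MARGIN_DB = 10.0
VAD_CAP_DB = -20.0
VAD_EPS = 1e-12


def reference_vad(audio: np.ndarray, audio_rate: float, n_frames: int) -> LabelSequence:
    """Energy-threshold VAD on the acoustic track, on the neural frame grid.

    The audio is resampled to 16 kHz and framed with 50 ms windows / 10 ms
    shift.  Log energy (dB) is smoothed with a trailing 5-frame moving
    average; a frame is speech when the smoothed energy exceeds
    ``min(20th percentile + 10 dB, -20 dBFS)`` — the percentile tracks the
    noise floor, the absolute cap keeps loud always-on signals detectable.
    """
    audio = np.asarray(audio, dtype=np.float64).ravel()
    if n_frames <= 0:
        return LabelSequence(np.empty(0, dtype=np.int64))
    if audio_rate != VAD_RATE:
        from fractions import Fraction
        frac = Fraction(VAD_RATE, int(round(audio_rate))).limit_denominator(1000)
        audio = signal.resample_poly(audio, frac.numerator, frac.denominator)
    win = int(0.050 * VAD_RATE)
    shift = int(0.010 * VAD_RATE)
    n_avail = max((len(audio) - win) // shift + 1, 0) if len(audio) >= win else 0

    energy = np.full(n_frames, 10 * np.log10(VAD_EPS))
    for t in range(min(n_frames, n_avail)):
        seg = audio[t * shift:t * shift + win]
        energy[t] = 10 * np.log10(np.mean(seg * seg) + VAD_EPS)
    kernel = np.ones(VAD_SMOOTH_FRAMES) / VAD_SMOOTH_FRAMES
    padded = np.concatenate([np.full(VAD_SMOOTH_FRAMES - 1, energy[0] if n_frames else 0.0), energy])
    smoothed = np.convolve(padded, kernel, mode="valid")
    threshold = min(np.percentile(smoothed, VAD_NOISE_PERCENTILE) + VAD_MARGIN_DB, VAD_CAP_DB)
    labels = (smoothed > threshold).astype(np.int64)
    return LabelSequence(labels)


def make_day_session(day_id: str, rec, truth: GroundTruth,
                     audio: np.ndarray | None = None,
                     audio_rate: float = 48000.0,
                     selected_channels: list[str] | None = None) -> DaySession:
    """Prepare one raw recording day for evaluation.

    Applies CAR preprocessing and high-gamma feature extraction, splits off
    the baseline (syllable-task) segment named in the ground truth, and
    derives reference labels from the audio surrogate (ground-truth labels
    when no audio is given).
    """
    from .features import extract_hg_power, preprocess_raw

    selected = selected_channels or [ch for ch in rec.channel_ids
                                     if ch not in set(rec.bad_channels)]
    frames = extract_hg_power(preprocess_raw(rec, selected))
    if truth.baseline_interval is None:
        raise ValueError("ground truth does not mark a baseline interval")
    b0, b1 = truth.baseline_interval
    shift_s = frames.frame_shift_ms / 1000.0
    f1 = int((b1 - frames.window_ms / 1000.0) / shift_s)  # windows fully inside
    baseline = frames.with_values(frames.values[:f1])
    if audio is not None:
        reference = reference_vad(audio, audio_rate, len(frames))
    else:
        reference = truth.vad
    return DaySession(day_id=day_id, frames=frames, baseline_frames=baseline,
                      truth=truth, reference=reference)
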