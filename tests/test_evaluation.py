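"""Metrics, grid search, channel contributions, and the reference VAD."""

import numpy as np
import pandas as pd
import pytest

from nvad.evaluation import (
    alignment_error,
    channel_contributions,
    frame_rates,
    grid_search_hyperparams,
    reference_vad,
    run_lodo_cv,
    trial_metrics,
)
from nvad.classifiers import TrainingConfig
from nvad.ticc import MRFCluster, TICCHyperparams, TICCModel
from nvad.types import GroundTruth, LabelSequence


def _seq(bits):
    return LabelSequence(np.asarray(list(bits), dtype=np.int64))


def levenshtein_dp(a, b):
    """Textbook edit-distance oracle (row-wise DP)."""
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


class TestAlignmentError:
    def test_identical_is_zero(self):
        assert alignment_error(_seq("0101"), _seq("0101")) == 0.0

    def test_all_zero_prediction_costs_speech_frames(self):
        target = _seq("0011100110")
        pred = _seq("0" * 10)
        assert alignment_error(pred, target) == 10.0 * 5

    def test_shifted_segment_example(self):
        assert alignment_error(_seq("001110"), _seq("000111")) == 20.0

    def test_matches_textbook_dp_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 2, rng.integers(0, 60))
            b = rng.integers(0, 2, rng.integers(0, 60))
            expected = 10.0 * levenshtein_dp(a.tolist(), b.tolist())
            assert alignment_error(LabelSequence(a), LabelSequence(b)) == expected

    def test_metric_properties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seqs = [LabelSequence(rng.integers(0, 2, rng.integers(1, 40)))
                    for _ in range(3)]
            a, b, c = seqs
            assert alignment_error(a, b) == alignment_error(b, a)
            assert alignment_error(a, c) <= alignment_error(a, b) + alignment_error(b, c)
            assert alignment_error(a, a) == 0.0
            assert alignment_error(a, b) <= 10.0 * max(len(a), len(b))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            alignment_error(LabelSequence(np.array([0, 2])), _seq("00"))


class TestFrameRates:
    def test_perfect_and_all_speech(self):
        t = _seq("00110")
        assert frame_rates(t, t) == (1.0, 0.0)
        assert frame_rates(_seq("11111"), t) == (1.0, 1.0)

    def test_hand_counted_example(self):
        det, fa = frame_rates(_seq("0101"), _seq("0011"))
        assert det == 0.5 and fa == 0.5

    def test_absent_denominators_are_none(self):
        det, fa = frame_rates(_seq("000"), _seq("000"))
        assert det is None and fa == 0.0
        det, fa = frame_rates(_seq("111"), _seq("111"))
        assert det == 1.0 and fa is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frame_rates(_seq("01"), _seq("011"))


def _truth_from_bits(bits, trial_bounds):
    rows = []
    for k, (cue, on, off) in enumerate(trial_bounds):
        rows.append({"trial_index": k, "word_id": k, "cue_onset": cue / 100.0,
                     "speech_onset": on / 100.0, "speech_offset": off / 100.0})
    return GroundTruth(vad=_seq(bits), trials=pd.DataFrame(rows))


class TestTrialMetrics:
    def _three_trials(self):
        # 3 trials of 30 frames; speech frames 10-20 within each
        bits = ("0" * 10 + "1" * 10 + "0" * 10) * 3
        bounds = [(k * 30, k * 30 + 10, k * 30 + 20) for k in range(3)]
        return _truth_from_bits(bits, bounds)

    def test_perfect_prediction(self):
        truth = self._three_trials()
        tm = trial_metrics(truth.vad, truth)
        assert tm.per_trial_error_ms == [0.0, 0.0, 0.0]
        assert tm.majority_detection_rate == 1.0
        assert tm.n_not_detected == 0

    def test_all_non_speech_prediction(self):
        truth = self._three_trials()
        tm = trial_metrics(_seq("0" * 90), truth)
        assert tm.majority_detection_rate == 0.0
        assert tm.n_not_detected == 3

    def test_majority_rate_two_thirds(self):
        truth = self._three_trials()
        pred = np.zeros(90, dtype=np.int64)
        pred[10:16] = 1   # trial 0: 60% of speech frames
        pred[40:44] = 1   # trial 1: 40%
        pred[70:80] = 1   # trial 2: 100%
        tm = trial_metrics(LabelSequence(pred), truth)
        assert tm.majority_detection_rate == pytest.approx(2 / 3)

    def test_empty_trial_table_rejected(self):
        truth = self._three_trials()
        empty = GroundTruth(vad=truth.vad, trials=truth.trials.iloc[:0])
        with pytest.raises(ValueError):
            trial_metrics(truth.vad, empty)


class TestGridSearch:
    def test_single_point_grid(self, tiny_day):
        beta, lam, table = grid_search_hyperparams(
            tiny_day["z"], tiny_day["truth"], [50.0], [11e-4])
        assert (beta, lam) == (50.0, 11e-4)
        assert len(table) == 1

    def test_table_covers_grid_and_best_is_argmin(self, tiny_day):
        beta, lam, table = grid_search_hyperparams(
            tiny_day["z"], tiny_day["truth"], [0.0, 50.0], [11e-4, 0.1])
        assert len(table) == 4
        best_row = table.loc[table["median_error_ms"].idxmin()]
        assert (beta, lam) == (best_row["beta"], best_row["lam"])


class TestChannelContributions:
    def _model(self, theta0, theta1, w=1):
        clusters = [MRFCluster(np.zeros(theta0.shape[0]), t, 0.0)
                    for t in (theta0, theta1)]
        return TICCModel(clusters=clusters, hyper=TICCHyperparams(K=2, n_layers=w))

    def test_identical_precisions_give_zero_map(self):
        theta = np.eye(4)
        cmap = channel_contributions(self._model(theta, theta.copy()))
        assert np.allclose(cmap.per_channel_contribution, 0.0)
        assert np.allclose(cmap.per_channel_interdependency, 0.0)

    def test_differences_localized_to_channel_subset(self):
        theta0 = np.eye(6)
        theta1 = np.eye(6)
        subset = [1, 4]
        theta1[1, 4] = theta1[4, 1] = 0.5
        theta1[1, 1] = 2.0
        cmap = channel_contributions(self._model(theta0, theta1))
        top2 = set(np.argsort(cmap.per_channel_interdependency)[-2:].tolist())
        assert top2 == set(subset)
        assert int(np.argmax(cmap.per_channel_contribution)) == 1

    def test_requires_two_clusters(self):
        theta = np.eye(3)
        model = TICCModel(clusters=[MRFCluster(np.zeros(3), theta, 0.0)],
                          hyper=TICCHyperparams(K=1))
        with pytest.raises(ValueError):
            channel_contributions(model)


class TestReferenceVAD:
    def test_digital_silence_is_all_non_speech(self):
        labels = reference_vad(np.zeros(48000 * 2), 48000.0, 195)
        assert np.all(labels.labels == 0)

    def test_constant_full_scale_noise_is_speech_after_warmup(self):
        rng = np.random.default_rng(2)
        labels = reference_vad(rng.uniform(-1, 1, 48000 * 2), 48000.0, 195)
        assert np.all(labels.labels[10:] == 1)

    def test_synthetic_session_bursts_detected(self, tiny_day):
        ref = tiny_day["day"].reference
        truth = tiny_day["truth"].vad
        det, fa = frame_rates(ref, truth)
        assert det >= 0.95
        assert fa <= 0.05


class TestLODO:
    def _days(self):
        from nvad.evaluation import make_day_session
        from nvad.synthetic import SessionConfig, generate_raw_session

        days = []
        for d in range(3):
            cfg = SessionConfig(n_channels=16, n_grids=2, n_trials=4,
                                baseline_duration=10.0, seed=200 + d)
            rec, truth, _ = generate_raw_session(cfg)
            days.append(make_day_session(f"day{d}", rec, truth))
        return days

    def test_deterministic_and_beats_shuffled_control(self):
        days = self._days()
        cfg = TrainingConfig(arch="logreg", seed=0)
        a = run_lodo_cv(days, cfg, label_source="reference", seed=0)
        b = run_lodo_cv(days, cfg, label_source="reference", seed=0)
        assert a.per_trial_error_ms == b.per_trial_error_ms
        assert a.per_fold == b.per_fold
        control = run_lodo_cv(days, cfg, label_source="shuffled", seed=0)
        assert a.median_error_ms < control.median_error_ms

    def test_too_few_days_rejected(self):
        days = self._days()[:2]
        with pytest.raises(ValueError):
            run_lodo_cv(days, TrainingConfig(arch="logreg"), label_source="reference")

    def test_dev_day_excluded_from_folds(self):
        days = self._days() + self._days()[:1]
        days[3].day_id = "dev"
        report = run_lodo_cv(days, TrainingConfig(arch="logreg", seed=0),
                             label_source="reference", dev_day="dev")
        assert all(f["test_day"] != "dev" for f in report.per_fold)
        assert len(report.per_fold) == 3
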