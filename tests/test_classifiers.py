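"""Classifier training, prediction, streaming-state equivalence, gradients."""

import numpy as np
import pytest

from nvad.classifiers import (
    TrainingConfig,
    load_model,
    predict_offline,
    predict_step,
    save_model,
    train_classifier,
)
from nvad.classifiers._nn import Adam, CNNNet, LSTMNet, softmax_ce
from nvad.types import FrameSequence, LabelSequence


class TestGradients:
    """Finite-difference checks of the numpy backward passes."""

    def test_cnn_backward_matches_numeric_gradient(self):
        rng = np.random.default_rng(0)
        net = CNNNet((8, 7), 2, rng)
        x = rng.standard_normal((3, 1, 8, 7))
        y = np.array([0, 1, 1])

        def loss_at():
            logits, _ = net.forward(x)
            return softmax_ce(logits, y)[0]

        logits, cache = net.forward(x, want_cache=True)
        _, dlogits = softmax_ce(logits, y)
        grads = net.backward(dlogits, cache)
        eps = 1e-6
        for name in ("c1W", "c2b", "f1W", "f3W"):
            flat = net.params[name].ravel()
            for idx in rng.choice(flat.size, size=5, replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                up = loss_at()
                flat[idx] = old - eps
                down = loss_at()
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_lstm_backward_matches_numeric_gradient(self):
        rng = np.random.default_rng(1)
        net = LSTMNet(4, 2, hidden=6, rng=rng)
        xs = rng.standard_normal((5, 2, 4))
        ys = rng.integers(0, 2, (5, 2))
        state = net.init_state(2)

        def loss_at():
            logits, _, _ = net.forward_chunk(xs, state)
            return softmax_ce(logits.reshape(-1, 2), ys.reshape(-1))[0]

        logits, _, caches = net.forward_chunk(xs, state)
        _, dflat = softmax_ce(logits.reshape(-1, 2), ys.reshape(-1))
        grads = net.backward_chunk(dflat.reshape(5, 2, 2), caches)
        eps = 1e-6
        for name in ("Wx1", "Wh1", "b2", "Wo", "Wh2"):
            flat = net.params[name].ravel()
            for idx in rng.choice(flat.size, size=4, replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                up = loss_at()
                flat[idx] = old - eps
                down = loss_at()
                flat[idx] = old
                numeric = (up - down) / (2 * eps)
                assert grads[name].ravel()[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_adam_reduces_quadratic(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(200):
            opt.step({"w": 2 * params["w"]})
        assert np.linalg.norm(params["w"]) < 0.5


class TestTraining:
    def test_logreg_fits_separable_data(self, separable_pair):
        frames, labels = separable_pair
        model = train_classifier([(frames, labels)], [], TrainingConfig(arch="logreg", seed=0))
        assert model.training_log[0]["train_accuracy"] >= 0.99
        pred = predict_offline(model, frames)
        assert np.mean(pred.labels == labels.labels) >= 0.99

    def test_single_class_labels_rejected(self, separable_pair):
        frames, labels = separable_pair
        ones = labels.with_labels(np.ones_like(labels.labels))
        with pytest.raises(ValueError):
            train_classifier([(frames, ones)], [], TrainingConfig(arch="logreg"))

    def test_rnn_keeps_best_validation_epoch(self, separable_pair):
        frames, labels = separable_pair
        cfg = TrainingConfig(arch="rnn", epochs=3, lstm_hidden=8, seed=0)
        model = train_classifier([(frames, labels)], [(frames, labels)], cfg)
        vals = [e["val_loss"] for e in model.training_log]
        assert min(vals) <= vals[0]

    @pytest.mark.parametrize("arch", ["logreg", "cnn", "rnn"])
    def test_training_is_deterministic(self, arch, separable_pair):
        frames, labels = separable_pair
        cfg = dict(arch=arch, seed=3)
        if arch == "cnn":
            cfg["epochs"] = 1
        if arch == "rnn":
            cfg.update(epochs=1, lstm_hidden=8)
        pair = [(frames, labels)]
        a = train_classifier(pair, pair, TrainingConfig(**cfg))
        b = train_classifier(pair, pair, TrainingConfig(**cfg))
        for k in a.params:
            np.testing.assert_array_equal(np.asarray(a.params[k]), np.asarray(b.params[k]))

    def test_label_swap_swaps_confident_predictions(self, separable_pair):
        frames, labels = separable_pair
        flipped = labels.with_labels(1 - labels.labels)
        m1 = train_classifier([(frames, labels)], [], TrainingConfig(arch="logreg", seed=0))
        m2 = train_classifier([(frames, flipped)], [], TrainingConfig(arch="logreg", seed=0))
        p1 = predict_offline(m1, frames).labels
        p2 = predict_offline(m2, frames).labels
        assert np.mean(p1 == 1 - p2) >= 0.99


class TestPrediction:
    def test_empty_sequence(self, logreg_model):
        empty = FrameSequence(np.empty((0, logreg_model.n_channels)), normalized=True)
        assert len(predict_offline(logreg_model, empty)) == 0

    @pytest.mark.parametrize("arch", ["logreg", "cnn", "rnn"])
    def test_step_fold_equals_offline(self, arch, separable_pair):
        frames, labels = separable_pair
        cfg = dict(arch=arch, seed=0)
        if arch != "logreg":
            cfg.update(epochs=1)
        if arch == "rnn":
            cfg["lstm_hidden"] = 8
        model = train_classifier([(frames, labels)], [(frames, labels)],
                                 TrainingConfig(**cfg))
        offline = predict_offline(model, frames).labels
        state = None
        folded = []
        for t in range(len(frames)):
            lab, state = predict_step(model, frames.values[t], state)
            folded.append(lab)
        np.testing.assert_array_equal(offline, np.asarray(folded))

    def test_rnn_state_reset_changes_outputs(self, separable_pair):
        frames, labels = separable_pair
        model = train_classifier([(frames, labels)], [(frames, labels)],
                                 TrainingConfig(arch="rnn", epochs=1, lstm_hidden=8, seed=0))
        # continuous pass vs a reset just before t: hidden state must matter
        state = None
        for t in range(33):
            _, state = predict_step(model, frames.values[t], state)
        continuous_h1 = state["h1"].copy()
        state = None
        for t in range(30, 33):
            _, state = predict_step(model, frames.values[t], state)
        assert not np.allclose(continuous_h1, state["h1"])

    def test_state_from_other_model_rejected(self, logreg_model, separable_pair):
        frames, labels = separable_pair
        other = train_classifier([(frames, labels)], [], TrainingConfig(arch="logreg", seed=1))
        _, state = predict_step(other, np.zeros(other.n_channels), None)
        with pytest.raises(ValueError):
            predict_step(logreg_model, np.zeros(logreg_model.n_channels), state)

    def test_save_load_round_trip(self, tmp_path, logreg_model, two_days):
        path = tmp_path / "model.npz"
        save_model(logreg_model, path)
        loaded = load_model(path)
        z = two_days[0][0]
        np.testing.assert_array_equal(predict_offline(logreg_model, z).labels,
                                      predict_offline(loaded, z).labels)
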