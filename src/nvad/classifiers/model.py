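"""Frame-wise speech/non-speech classifiers.

Three architectures, all predicting one binary class per 10 ms feature frame:

* ``logreg`` — L1-regularized logistic regression (liblinear) on context-
  stacked frames (0 to -300 ms in 50 ms steps).
* ``cnn`` — LeNet-like convolutional network on the same stacked context,
  laid out as a channels x lags image; Adam, lr 1e-4, 10 epochs.
* ``rnn`` — two LSTM layers with 100 units and a linear 2-unit readout on
  unstacked frames; Adam, lr 3e-4, 20 epochs, truncated backpropagation
  through time with k1 = k2 = 50 frames, keeping the weights of the epoch
  with minimum validation loss.

``predict_offline`` is defined as the fold of ``predict_step`` over the
sequence, which makes offline and streaming inference identical by
construction (the stacked architectures keep a lag ring buffer in the
streaming state; the RNN keeps its hidden state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from ..features import DEFAULT_STACK_LAGS, stack_context
from ..types import BINARY_CLASSES, FrameSequence, LabelSequence
from ._nn import Adam, CNNNet, LSTMNet, softmax_ce

__all__ = [
    "TrainingConfig",
    "ClassifierModel",
    "train_classifier",
    "predict_offline",
    "predict_step",
    "save_model",
    "load_model",
]

_ARCH_DEFAULTS = {
    "logreg": {"learning_rate": None, "epochs": None},
    "cnn": {"learning_rate": 1e-4, "epochs": 10},
    "rnn": {"learning_rate": 3e-4, "epochs": 20},
}


@dataclass
class TrainingConfig:
    """Training settings; unset learning rate / epochs fall back to the
    per-architecture defaults above."""

    arch: str = "rnn"
    learning_rate: float | None = None
    epochs: int | None = None
    tbptt_k1: int = 50
    tbptt_k2: int = 50
    l1_strength: float = 1.0
    batch_size: int = 256
    seed: int = 0
    select_best_by_val: bool | None = None
    n_out: int = 2
    stack_lags: tuple[int, ...] = DEFAULT_STACK_LAGS
    lstm_hidden: int = 100

    def __post_init__(self) -> None:
        if self.arch not in _ARCH_DEFAULTS:
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.learning_rate is None:
            self.learning_rate = _ARCH_DEFAULTS[self.arch]["learning_rate"]
        if self.epochs is None:
            self.epochs = _ARCH_DEFAULTS[self.arch]["epochs"]
        if self.select_best_by_val is None:
            self.select_best_by_val = self.arch == "rnn"
        if self.arch != "logreg" and (self.epochs <= 0 or self.learning_rate <= 0):
            raise ValueError("epochs and learning_rate must be positive")


@dataclass
class ClassifierModel:
    """A trained classifier: architecture tag, opaque parameters, and the
    input contract (channel count plus stack lags for memoryless archs)."""

    arch: str
    params: dict
    input_spec: dict
    training_log: list = field(default_factory=list)
    seed: int = 0
    classes: dict[int, str] = field(default_factory=lambda: dict(BINARY_CLASSES))

    @property
    def n_channels(self) -> int:
        return self.input_spec["n_channels"]


# ---------------------------------------------------------------------------
# training

def _check_training_data(train, val, cfg):
    if not train:
        raise ValueError("no training sequences")
    n_ch = train[0][0].n_features
    all_labels = []
    for frames, labels in list(train) + list(val):
        if frames.n_features != n_ch:
            raise ValueError("inconsistent feature dimension across sequences")
        if len(frames) != len(labels):
            raise ValueError("frames and labels length mismatch")
        if not labels.is_binary:
            raise ValueError("training labels must be binary")
        all_labels.append(labels.labels)
    merged = np.concatenate(all_labels)
    if np.unique(merged).shape[0] < 2:
        raise ValueError("training labels contain a single class")
    if cfg.select_best_by_val and not val:
        raise ValueError("validation data required when select_best_by_val is set")
    return n_ch


def _stacked_matrix(seqs, lags):
    xs, ys = [], []
    for frames, labels in seqs:
        xs.append(stack_context(frames, lags).values)
        ys.append(labels.labels)
    return np.vstack(xs), np.concatenate(ys)


def _as_images(stacked_rows: np.ndarray, n_channels: int, n_lags: int) -> np.ndarray:
    """Stacked rows (lag-major blocks of C) -> (B, 1, C, n_lags) images."""
    B = stacked_rows.shape[0]
    return stacked_rows.reshape(B, n_lags, n_channels).transpose(0, 2, 1)[:, None, :, :]


def _train_logreg(train, val, cfg, n_ch):
    X, y = _stacked_matrix(train, cfg.stack_lags)
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / cfg.l1_strength,
                             solver="liblinear", random_state=cfg.seed, max_iter=1000)
    clf.fit(X, y)
    order = np.argsort(clf.classes_)
    coef = clf.coef_[0] if clf.classes_[order][1] == 1 else -clf.coef_[0]
    intercept = clf.intercept_[0] if clf.classes_[order][1] == 1 else -clf.intercept_[0]
    params = {"coef": coef.astype(np.float64), "intercept": float(intercept)}
    log = [{"train_accuracy": float(clf.score(X, y))}]
    return params, log


def _train_cnn(train, val, cfg, n_ch):
    L = len(cfg.stack_lags)
    X, y = _stacked_matrix(train, cfg.stack_lags)
    images = _as_images(X, n_ch, L)
    rng = np.random.default_rng(cfg.seed)
    net = CNNNet((n_ch, L), cfg.n_out, rng)
    opt = Adam(net.params, cfg.learning_rate)
    n = images.shape[0]
    log = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits, cache = net.forward(images[idx], want_cache=True)
            loss, dlogits = softmax_ce(logits, y[idx])
            opt.step(net.backward(dlogits, cache))
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val:
            Xv, yv = _stacked_matrix(val, cfg.stack_lags)
            logits, _ = net.forward(_as_images(Xv, n_ch, L))
            entry["val_loss"] = softmax_ce(logits, yv)[0]
        log.append(entry)
    return net.params, log


def _rnn_val_loss(net, val):
    total, count = 0.0, 0
    for frames, labels in val:
        xs = frames.values[:, None, :]
        state = net.init_state(1)
        logits, _, _ = net.forward_chunk(xs, state)
        loss, _ = softmax_ce(logits[:, 0, :], labels.labels)
        total += loss * len(frames)
        count += len(frames)
    return total / max(count, 1)


def _train_rnn(train, val, cfg, n_ch):
    rng = np.random.default_rng(cfg.seed)
    net = LSTMNet(n_ch, cfg.n_out, hidden=cfg.lstm_hidden, rng=rng)
    opt = Adam(net.params, cfg.learning_rate)
    # sequences of equal length run as one batch; k1 = k2 -> update every
    # chunk with hidden state carried over, detached across chunk boundaries
    by_len: dict[int, list[int]] = {}
    for i, (frames, _) in enumerate(train):
        by_len.setdefault(len(frames), []).append(i)
    groups = [by_len[k] for k in sorted(by_len)]
    k = cfg.tbptt_k1

    log = []
    best = None
    for epoch in range(cfg.epochs):
        losses = []
        for group in groups:
            xs = np.stack([train[i][0].values for i in group], axis=1)   # (T, B, C)
            ys = np.stack([train[i][1].labels for i in group], axis=1)   # (T, B)
            state = net.init_state(len(group))
            for start in range(0, xs.shape[0], k):
                chunk_x, chunk_y = xs[start:start + k], ys[start:start + k]
                logits, state, caches = net.forward_chunk(chunk_x, state)
                Tc, B, _ = logits.shape
                loss, dflat = softmax_ce(logits.reshape(Tc * B, -1), chunk_y.reshape(-1))
                opt.step(net.backward_chunk(dflat.reshape(Tc, B, -1), caches))
                losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val:
            entry["val_loss"] = float(_rnn_val_loss(net, val))
            if cfg.select_best_by_val and (best is None or entry["val_loss"] < best[0]):
                best = (entry["val_loss"], {kk: v.copy() for kk, v in net.params.items()})
        log.append(entry)
    params = best[1] if (cfg.select_best_by_val and best is not None) else net.params
    return params, log


def train_classifier(train: list[tuple[FrameSequence, LabelSequence]],
                     val: list[tuple[FrameSequence, LabelSequence]],
                     cfg: TrainingConfig) -> ClassifierModel:
    """Train one classifier on (frames, labels) sequences.

    ``train``/``val`` are lists of whole-session pairs.  Labels must be
    binary with both classes present.  Training is deterministic given
    ``cfg.seed``.
    """
    n_ch = _check_training_data(train, val, cfg)
    trainer = {"logreg": _train_logreg, "cnn": _train_cnn, "rnn": _train_rnn}[cfg.arch]
    params, log = trainer(list(train), list(val), cfg, n_ch)
    input_spec = {"n_channels": n_ch,
                  "stack_lags": list(cfg.stack_lags) if cfg.arch in ("logreg", "cnn") else None,
                  "n_out": cfg.n_out,
                  "lstm_hidden": cfg.lstm_hidden if cfg.arch == "rnn" else None}
    return ClassifierModel(arch=cfg.arch, params=params, input_spec=input_spec,
                           training_log=log, seed=cfg.seed)


# ---------------------------------------------------------------------------
# inference (streaming-first: offline prediction folds predict_step)

def _fresh_state(model: ClassifierModel) -> dict:
    if model.arch == "rnn":
        net = _rnn_from_model(model)
        st = net.init_state(1)
        st["_tag"] = id(model)
        return st
    lags = model.input_spec["stack_lags"]
    size = max(lags) + 1
    return {"_tag": id(model), "t": 0,
            "buffer": np.zeros((size, model.n_channels))}


def _rnn_from_model(model: ClassifierModel) -> LSTMNet:
    net = LSTMNet.__new__(LSTMNet)
    net.n_in = model.n_channels
    net.n_out = model.input_spec["n_out"]
    net.hidden = model.input_spec["lstm_hidden"]
    net.params = model.params
    return net


def _cnn_from_model(model: ClassifierModel) -> CNNNet:
    net = CNNNet.__new__(CNNNet)
    net.in_shape = (model.n_channels, len(model.input_spec["stack_lags"]))
    net.params = model.params
    return net


def predict_step(model: ClassifierModel, frame: np.ndarray, state: dict | None):
    """Classify a single frame, threading the streaming state.

    ``state=None`` starts a fresh stream.  Folding this function over a
    sequence reproduces :func:`predict_offline` exactly.
    """
    x = np.asarray(frame, dtype=np.float64).ravel()
    if x.shape[0] != model.n_channels:
        raise ValueError(f"frame has {x.shape[0]} features, model expects {model.n_channels}")
    if state is None:
        state = _fresh_state(model)
    elif state.get("_tag") != id(model):
        raise ValueError("streaming state does not belong to this model")

    if model.arch == "rnn":
        net = _rnn_from_model(model)
        logits, new_core = net.step(x[None, :], state)
        new_state = {**new_core, "_tag": state["_tag"]}
        return int(np.argmax(logits[0])), new_state

    lags = model.input_spec["stack_lags"]
    size = max(lags) + 1
    buffer = state["buffer"].copy()
    t = state["t"]
    buffer[t % size] = x
    stacked = np.concatenate([buffer[(t - lag) % size] for lag in lags])
    new_state = {"_tag": state["_tag"], "t": t + 1, "buffer": buffer}

    if model.arch == "logreg":
        margin = float(stacked @ model.params["coef"] + model.params["intercept"])
        return int(margin > 0), new_state
    net = _cnn_from_model(model)
    image = _as_images(stacked[None, :], model.n_channels, len(lags))
    logits, _ = net.forward(image)
    return int(np.argmax(logits[0])), new_state


def predict_offline(model: ClassifierModel, frames: FrameSequence) -> LabelSequence:
    """Per-frame classes for a whole (unstacked) feature sequence.

    Defined as the fold of :func:`predict_step`, so streaming replays of the
    same features yield the identical class sequence frame for frame.
    """
    if not frames.normalized:
        import logging
        logging.getLogger(__name__).warning("predicting on non-normalized features")
    labels = np.empty(len(frames), dtype=np.int64)
    state = None
    for t in range(len(frames)):
        labels[t], state = predict_step(model, frames.values[t], state)
    return LabelSequence(labels, frame_shift_ms=frames.frame_shift_ms,
                         start_time=frames.start_time, classes=dict(BINARY_CLASSES))


# ---------------------------------------------------------------------------
# persistence (npz + json header)

def save_model(model: ClassifierModel, path: str | Path) -> None:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    meta = {"arch": model.arch, "input_spec": model.input_spec,
            "training_log": model.training_log, "seed": model.seed,
            "classes": {str(k): v for k, v in model.classes.items()}}
    arrays = {k: np.asarray(v) for k, v in model.params.items()}
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        params = {k: data[k] for k in data.files if k != "_meta"}
    params = {k: (float(v) if v.ndim == 0 else v) for k, v in params.items()}
    return ClassifierModel(arch=meta["arch"], params=params, input_spec=meta["input_spec"],
                           training_log=meta["training_log"], seed=meta["seed"],
                           classes={int(k): v for k, v in meta["classes"].items()})
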