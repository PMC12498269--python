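"""Real-time pipeline: a DAG of stateful processing nodes.

The default graph is the chain ingest -> CAR -> band-pass/notch -> framer ->
z-score -> classifier -> emitter (-> logger).  Every node carries explicit
state (filter delay lines, the framer's sample buffer, the classifier's lag
ring buffer or LSTM hidden state), no node ever reads ahead of the samples
it has been given, and the framer emits a frame exactly when the last sample
of its 50 ms window arrives.  As a consequence the emitted class sequence is
invariant to how the sample stream is chunked and identical, frame for
frame, to offline prediction on the same recording.

Per-node processing latencies are measured and attached to each event for
reporting; they are hardware-dependent and never part of any contract.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .classifiers import ClassifierModel, predict_step
from .features import hg_filter_cascade, log_window_power
from .types import BaselineStats

__all__ = [
    "StreamConfig",
    "StreamEvent",
    "StreamNode",
    "build_pipeline",
    "push_samples",
    "replay_log",
    "Pipeline",
]


@dataclass
class StreamConfig:
    """Static configuration of the ingest/preprocessing front end."""

    sample_rate: float
    channel_ids: list[str]
    grid_of_channel: np.ndarray
    baseline_stats: BaselineStats | None
    bad_channels: list[str] = field(default_factory=list)
    selected_channels: list[str] | None = None
    window_ms: float = 50.0
    shift_ms: float = 10.0


@dataclass
class StreamEvent:
    frame_index: int
    time: float
    label: int
    latencies_ms: dict[str, float] = field(default_factory=dict)


class StreamNode:
    """One self-contained processing step: one message in, zero+ out."""

    name = "node"

    def process(self, msg):  # pragma: no cover - interface
        raise NotImplementedError


class PreprocessNode(StreamNode):
    name = "car"

    def __init__(self, cfg: StreamConfig):
        self.n_raw = len(cfg.channel_ids)
        bad = set(cfg.bad_channels)
        self.keep = [i for i, ch in enumerate(cfg.channel_ids) if ch not in bad]
        ids = [cfg.channel_ids[i] for i in self.keep]
        grids = np.asarray(cfg.grid_of_channel)[self.keep]
        self.grid_cols = [np.flatnonzero(grids == g) for g in np.unique(grids)]
        selected = cfg.selected_channels or ids
        for ch in selected:
            if ch in bad:
                raise ValueError(f"selected channel {ch!r} is marked bad")
        self.order = [ids.index(ch) for ch in selected]

    def process(self, chunk: np.ndarray):
        data = chunk[:, self.keep].copy()
        for cols in self.grid_cols:
            data[:, cols] -= data[:, cols].mean(axis=1, keepdims=True)
        return [data[:, self.order]]


class FilterNode(StreamNode):
    """Causal SOS cascade with persistent per-channel delay lines."""

    name = "filter"

    def __init__(self, sos: np.ndarray, n_channels: int):
        self.sos = sos
        self.zi = np.zeros((sos.shape[0], 2, n_channels))

    def process(self, chunk: np.ndarray):
        out, self.zi = signal.sosfilt(self.sos, chunk, axis=0, zi=self.zi)
        return [out]


class FramerNode(StreamNode):
    """Buffers filtered samples; emits one log-power feature per complete
    window, advancing by the frame shift.  Keeps window - shift samples."""

    name = "framer"

    def __init__(self, cfg: StreamConfig, n_channels: int):
        self.win = int(round(cfg.window_ms * cfg.sample_rate / 1000.0))
        self.shift = int(round(cfg.shift_ms * cfg.sample_rate / 1000.0))
        self.buffer = np.empty((0, n_channels))
        self.frame_index = 0

    def process(self, chunk: np.ndarray):
        self.buffer = np.concatenate([self.buffer, chunk], axis=0)
        out = []
        while self.buffer.shape[0] >= self.win:
            features = log_window_power(self.buffer[: self.win])
            out.append((self.frame_index, features))
            self.frame_index += 1
            self.buffer = self.buffer[self.shift:]
        return out


class ZScoreNode(StreamNode):
    name = "zscore"

    def __init__(self, stats: BaselineStats):
        self.stats = stats

    def process(self, msg):
        idx, features = msg
        return [(idx, (features - self.stats.mean) / self.stats.sd)]


class ClassifierNode(StreamNode):
    name = "classifier"

    def __init__(self, model: ClassifierModel):
        self.model = model
        self.state = None

    def process(self, msg):
        idx, features = msg
        label, self.state = predict_step(self.model, features, self.state)
        return [(idx, label)]


class EmitterNode(StreamNode):
    name = "emitter"

    def __init__(self, shift_s: float):
        self.shift_s = shift_s

    def process(self, msg):
        idx, label = msg
        return [StreamEvent(frame_index=idx, time=idx * self.shift_s, label=int(label))]


class LoggerNode(StreamNode):
    name = "logger"

    def __init__(self, path: str | Path | None):
        self.path = Path(path) if path is not None else None
        if self.path is not None:
            self.path.write_text("")

    def process(self, event: StreamEvent):
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps({
                    "frame_index": event.frame_index, "time": event.time,
                    "label": event.label, "latencies_ms": event.latencies_ms,
                }) + "\n")
        return [event]


@dataclass
class Pipeline:
    nodes: list[StreamNode]
    edges: list[tuple[str, str]]


def _check_acyclic(nodes: list[StreamNode], edges: list[tuple[str, str]]) -> None:
    order = {n.name: i for i, n in enumerate(nodes)}
    unknown = [e for e in edges if e[0] not in order or e[1] not in order]
    if unknown:
        raise ValueError(f"edges reference unknown nodes: {unknown}")
    # chain pipelines are validated as a DAG by requiring a topological order
    if any(order[a] >= order[b] for a, b in edges):
        raise ValueError("pipeline graph contains a cycle or backward edge")


def build_pipeline(model: ClassifierModel, config: StreamConfig,
                   log_path: str | Path | None = None) -> Pipeline:
    """Assemble the default processing chain with fresh node states."""
    if config.baseline_stats is None:
        raise ValueError("baseline statistics are required to build a pipeline")
    pre = PreprocessNode(config)
    n_sel = len(pre.order)
    if model.n_channels != n_sel:
        raise ValueError(f"model expects {model.n_channels} channels, "
                         f"pipeline selects {n_sel}")
    if config.baseline_stats.mean.shape[0] != n_sel:
        raise ValueError("baseline statistics do not match selected channels")
    nodes = [
        pre,
        FilterNode(hg_filter_cascade(config.sample_rate), n_sel),
        FramerNode(config, n_sel),
        ZScoreNode(config.baseline_stats),
        ClassifierNode(model),
        EmitterNode(config.shift_ms / 1000.0),
        LoggerNode(log_path),
    ]
    edges = [(a.name, b.name) for a, b in zip(nodes[:-1], nodes[1:])]
    _check_acyclic(nodes, edges)
    return Pipeline(nodes=nodes, edges=edges)


def push_samples(pipeline: Pipeline, chunk: np.ndarray) -> list[StreamEvent]:
    """Feed a block of raw samples; returns one event per completed frame."""
    chunk = np.asarray(chunk, dtype=np.float64)
    if chunk.ndim != 2:
        raise ValueError("chunk must be 2-D (n_samples, n_channels)")
    front = pipeline.nodes[0]
    if chunk.shape[1] != front.n_raw:
        raise ValueError(f"chunk has {chunk.shape[1]} channels, expected {front.n_raw}")
    compute_nodes = [n for n in pipeline.nodes if not isinstance(n, LoggerNode)]
    loggers = [n for n in pipeline.nodes if isinstance(n, LoggerNode)]
    msgs = [chunk]
    latencies: dict[str, float] = {}
    for node in compute_nodes:
        t0 = time.perf_counter()
        out = []
        for m in msgs:
            out.extend(node.process(m))
        latencies[node.name] = (time.perf_counter() - t0) * 1000.0
        msgs = out
    for event in msgs:
        event.latencies_ms = dict(latencies)
        for logger_node in loggers:
            logger_node.process(event)
    return msgs


def replay_log(path: str | Path) -> list[StreamEvent]:
    """Reconstruct the emitted event sequence from a pipeline log file."""
    events = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                events.append(StreamEvent(frame_index=int(rec["frame_index"]),
                                          time=float(rec["time"]),
                                          label=int(rec["label"]),
                                          latencies_ms=rec.get("latencies_ms", {})))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"corrupt log line {lineno}: {exc}") from exc
    return events
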