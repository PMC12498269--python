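"""Readers and writers for the formats the tool touches.

Recordings travel as MATLAB v5 ``.mat`` files (samples x channels plus
metadata), audio as WAV, labels and trial tables as delimited text.  A
dataset manifest (YAML) ties the per-day files together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import loadmat, savemat, wavfile

from .types import GroundTruth, LabelSequence, RawRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_wav",
    "read_wav",
    "write_labels",
    "read_labels",
    "write_ground_truth",
    "read_ground_truth",
    "DatasetManifest",
    "load_manifest",
]

DEFAULT_MAT_SPEC = {
    "samples": "samples",
    "sample_rate": "sample_rate",
    "channel_ids": "channel_ids",
    "grid_of_channel": "grid_of_channel",
    "bad_channels": "bad_channels",
}


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Store a recording as a MATLAB v5 file."""
    savemat(str(path), {
        "samples": rec.samples,
        "sample_rate": np.array([[rec.sample_rate]]),
        "channel_ids": np.array(rec.channel_ids, dtype=object),
        "grid_of_channel": rec.grid_of_channel.astype(np.float64),
        "bad_channels": np.array(rec.bad_channels, dtype=object),
    }, format="5")


def _mat_strings(value) -> list[str]:
    arr = np.atleast_1d(np.squeeze(value)) if value is not None else np.empty(0)
    return [str(np.squeeze(v)) for v in arr] if arr.size else []


def read_recording(path: str | Path, spec: dict[str, str] | None = None) -> RawRecording:
    """Load a recording from a MATLAB v5 file.

    ``spec`` maps the logical fields (samples, sample_rate, ...) to the
    variable names inside the file; missing variables raise a named error.
    """
    spec = {**DEFAULT_MAT_SPEC, **(spec or {})}
    data = loadmat(str(path))
    for logical in ("samples", "sample_rate"):
        if spec[logical] not in data:
            raise KeyError(f"MAT file {path} is missing variable {spec[logical]!r}")
    samples = np.asarray(data[spec["samples"]], dtype=np.float64)
    sample_rate = float(np.squeeze(data[spec["sample_rate"]]))
    n_ch = samples.shape[1]
    channel_ids = (_mat_strings(data.get(spec["channel_ids"]))
                   or [f"ch{i:03d}" for i in range(n_ch)])
    grid = (np.squeeze(np.asarray(data[spec["grid_of_channel"]], dtype=np.int64))
            if spec["grid_of_channel"] in data else np.zeros(n_ch, dtype=np.int64))
    bad = _mat_strings(data.get(spec["bad_channels"]))
    return RawRecording(samples=samples, sample_rate=sample_rate,
                        channel_ids=channel_ids, grid_of_channel=np.atleast_1d(grid),
                        bad_channels=bad)


def write_wav(audio: np.ndarray, rate: float, path: str | Path) -> None:
    wavfile.write(str(path), int(rate), audio.astype(np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float64 in [-1, 1] (PCM16 or float payloads)."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    if data.ndim > 1:
        data = data[:, 0]
    return data, float(rate)


def write_labels(labels: LabelSequence, path: str | Path) -> None:
    """Delimited text: header comments with metadata, then one row per frame."""
    with Path(path).open("w") as fh:
        fh.write(f"# frame_shift_ms={labels.frame_shift_ms}\n")
        fh.write(f"# start_time={labels.start_time}\n")
        fh.write(f"# classes={json.dumps({str(k): v for k, v in labels.classes.items()})}\n")
        fh.write("frame_index\ttime_s\tlabel\n")
        shift_s = labels.frame_shift_ms / 1000.0
        for i, lab in enumerate(labels.labels):
            fh.write(f"{i}\t{labels.start_time + i * shift_s:.3f}\t{int(lab)}\n")


def read_labels(path: str | Path) -> LabelSequence:
    meta = {"frame_shift_ms": 10.0, "start_time": 0.0, "classes": {}}
    values = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key == "classes":
                    meta["classes"] = {int(k): v for k, v in json.loads(val).items()}
                elif key in meta:
                    meta[key] = float(val)
                continue
            if line.startswith("frame_index") or not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed label row at line {lineno}: {line!r}")
            try:
                values.append(int(parts[2]))
            except ValueError as exc:
                raise ValueError(f"malformed label row at line {lineno}: {line!r}") from exc
    return LabelSequence(np.asarray(values, dtype=np.int64),
                         frame_shift_ms=meta["frame_shift_ms"],
                         start_time=meta["start_time"],
                         classes=meta["classes"] or {0: "non-speech", 1: "speech"})


def write_ground_truth(truth: GroundTruth, vad_path: str | Path, trials_path: str | Path) -> None:
    write_labels(truth.vad, vad_path)
    table = truth.trials.copy()
    if truth.baseline_interval is not None:
        table.attrs["baseline_interval"] = truth.baseline_interval
    with Path(trials_path).open("w") as fh:
        if truth.baseline_interval is not None:
            b0, b1 = truth.baseline_interval
            fh.write(f"# baseline_interval={b0},{b1}\n")
        table.to_csv(fh, index=False)


def read_ground_truth(vad_path: str | Path, trials_path: str | Path) -> GroundTruth:
    vad = read_labels(vad_path)
    baseline = None
    with Path(trials_path).open() as fh:
        first = fh.readline()
        if first.startswith("# baseline_interval="):
            b0, b1 = first.strip().split("=")[1].split(",")
            baseline = (float(b0), float(b1))
            trials = pd.read_csv(fh)
        else:
            fh.seek(0)
            trials = pd.read_csv(fh)
    return GroundTruth(vad=vad, trials=trials, baseline_interval=baseline)


@dataclass
class DatasetManifest:
    """Per-day file listing plus role assignments for cross-validation."""

    days: list[dict]
    roles: dict[str, list[str]] = field(default_factory=dict)
    selected_channels: list[str] | None = None
    bad_channels: list[str] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        assigned: list[str] = []
        for role, ids in self.roles.items():
            overlap = set(ids) & set(assigned)
            if overlap:
                raise ValueError(f"day(s) {sorted(overlap)} assigned to multiple roles")
            assigned.extend(ids)
        for day in self.days:
            for key in ("recording", "audio", "vad", "trials"):
                if day.get(key) and not (self.root / day[key]).exists():
                    raise FileNotFoundError(f"{day['day_id']}: missing file {day[key]}")


def load_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return DatasetManifest(days=raw.get("days", []),
                           roles=raw.get("roles", {}),
                           selected_channels=raw.get("selected_channels"),
                           bad_channels=raw.get("bad_channels", []),
                           root=path.parent)
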