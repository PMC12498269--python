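"""Turning cluster assignments into speech / non-speech training labels.

The experiment design guarantees that most of each session is silent, so of
the two clusters the one occupying less total time is taken to be speech.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import BINARY_CLASSES, NON_SPEECH, SPEECH, LabelSequence, SegmentList

__all__ = [
    "labels_to_segments",
    "segments_to_labels",
    "infer_class_map",
    "relabel",
]

logger = logging.getLogger(__name__)


def labels_to_segments(labels: LabelSequence) -> SegmentList:
    """Run-length encode a label sequence into half-open (start, end, label) runs."""
    lab = labels.labels
    if lab.shape[0] == 0:
        return SegmentList([])
    boundaries = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [lab.shape[0]]])
    return SegmentList([(int(s), int(e), int(lab[s])) for s, e in zip(starts, ends)])


def segments_to_labels(segs: SegmentList, T: int,
                       frame_shift_ms: float = 10.0, start_time: float = 0.0,
                       classes: dict[int, str] | None = None) -> LabelSequence:
    """Inverse of :func:`labels_to_segments`; segments must tile [0, T)."""
    if segs.total_frames != T:
        raise ValueError(f"segments cover {segs.total_frames} frames, expected {T}")
    labels = np.empty(T, dtype=np.int64)
    for start, end, label in segs.segments:
        labels[start:end] = label
    return LabelSequence(labels, frame_shift_ms=frame_shift_ms, start_time=start_time,
                         classes=classes or {})


def infer_class_map(cluster_labels: LabelSequence,
                    rule: str = "total_duration") -> dict[int, int]:
    """Decide which cluster is speech from subsequence lengths.

    With ``rule="total_duration"`` (default) the cluster with the smaller
    total assigned time becomes speech — sessions are mostly silent, so the
    minority cluster is the speaking one.  ``rule="mean_run_length"`` uses
    the mean run length instead.  Exact ties label the lower cluster index
    speech; a single-cluster sequence maps to non-speech only.
    """
    lab = cluster_labels.labels
    present = np.unique(lab)
    if len(present) == 1:
        logger.warning("only one cluster present; mapping it to non-speech")
        return {int(present[0]): NON_SPEECH}
    if len(present) != 2:
        raise ValueError(f"expected 2 clusters, found {len(present)}")

    if rule == "total_duration":
        sizes = {int(k): int(np.count_nonzero(lab == k)) for k in present}
    elif rule == "mean_run_length":
        segs = labels_to_segments(cluster_labels)
        sizes = {}
        for k in present:
            runs = [e - s for s, e, l in segs.segments if l == k]
            sizes[int(k)] = float(np.mean(runs))
    else:
        raise ValueError(f"unknown rule {rule!r}")

    a, b = (int(k) for k in present)
    if sizes[a] == sizes[b]:
        logger.warning("exact tie between clusters; labeling lower index as speech")
        speech = min(a, b)
    else:
        speech = a if sizes[a] < sizes[b] else b
    other = b if speech == a else a
    frac = np.count_nonzero(lab == speech) / lab.shape[0]
    logger.info("speech cluster %d covers %.1f%% of the session", speech, 100 * frac)
    return {speech: SPEECH, other: NON_SPEECH}


def relabel(cluster_labels: LabelSequence, class_map: dict[int, int]) -> LabelSequence:
    """Apply a cluster -> {0, 1} map, producing a binary label sequence."""
    lab = cluster_labels.labels
    unmapped = set(np.unique(lab).tolist()) - set(class_map)
    if unmapped:
        raise ValueError(f"labels without a class mapping: {sorted(unmapped)}")
    lut_size = max(class_map) + 1 if class_map else 1
    lut = np.zeros(lut_size, dtype=np.int64)
    for k, v in class_map.items():
        lut[k] = v
    return cluster_labels.with_labels(lut[lab], classes=dict(BINARY_CLASSES))
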