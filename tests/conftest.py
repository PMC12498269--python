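"""Shared fixtures: small synthetic sessions and trained models.

Expensive artifacts are session-scoped; everything is generated
programmatically with fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from nvad.classifiers import TrainingConfig, train_classifier
from nvad.evaluation import make_day_session
from nvad.features import apply_zscore, fit_baseline_stats
from nvad.synthetic import SessionConfig, generate_raw_session


@pytest.fixture(scope="session")
def tiny_day():
    """One small raw day (16 channels, 4 trials) with features and truth."""
    cfg = SessionConfig(n_channels=16, n_grids=2, n_trials=4,
                        baseline_duration=10.0, seed=5)
    rec, truth, audio = generate_raw_session(cfg)
    day = make_day_session("tiny", rec, truth, audio=audio)
    stats = fit_baseline_stats(day.baseline_frames, source="tiny")
    z = apply_zscore(day.frames, stats)
    return {"config": cfg, "rec": rec, "truth": truth, "audio": audio,
            "day": day, "stats": stats, "z": z}


@pytest.fixture(scope="session")
def two_days():
    """Two small days (z-scored frames, ground-truth labels) for training."""
    out = []
    for seed in (0, 1):
        cfg = SessionConfig(n_channels=16, n_grids=2, n_trials=6,
                            baseline_duration=12.0, seed=seed)
        rec, truth, _ = generate_raw_session(cfg)
        day = make_day_session(f"d{seed}", rec, truth)
        z = apply_zscore(day.frames, fit_baseline_stats(day.baseline_frames))
        out.append((z, truth.vad))
    return out


@pytest.fixture(scope="session")
def logreg_model(two_days):
    return train_classifier(two_days[:1], two_days[1:], TrainingConfig(arch="logreg", seed=0))


@pytest.fixture(scope="session")
def separable_pair():
    """Linearly separable stacked-feature training data with a wide margin."""
    from nvad.types import FrameSequence, LabelSequence

    rng = np.random.default_rng(7)
    T, C = 400, 8
    labels = (rng.random(T) < 0.5).astype(np.int64)
    x = rng.standard_normal((T, C)) * 0.1
    x[:, 0] += np.where(labels == 1, 5.0, -5.0)
    frames = FrameSequence(x, channel_ids=[f"f{i}" for i in range(C)], normalized=True)
    return frames, LabelSequence(labels)
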