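"""Shared fixtures: synthetic training data and small rendered videos."""
from __future__ import annotations

import numpy as np
import pytest

from flygroom import fit_knn
from flygroom.pipeline import (BENCHMARK_BEHAVIORS, BENCHMARK_BOUT_MEANS,
                               RunConfig, synthetic_training_set)
from flygroom.synthetic import (FlyAppearance, GroundTruthEthogram,
                                default_roi, generate_ethogram_script,
                                render_video)

TRAINING_SEED = 1234  # disjoint from every benchmark/video seed used in tests


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def training_set():
    return synthetic_training_set(seed=TRAINING_SEED, n_videos=3,
                                  duration_s=120.0)


@pytest.fixture(scope="session")
def knn_model(training_set):
    return fit_knn(training_set, k=10)


@pytest.fixture(scope="session")
def default_appearance():
    return FlyAppearance()


def make_script(duration_s: float, seed: int,
                behaviors=BENCHMARK_BEHAVIORS) -> GroundTruthEthogram:
    """Three-class benchmark script with field-typical bout means."""
    return generate_ethogram_script(duration_s,
                                    bout_means_s=BENCHMARK_BOUT_MEANS,
                                    behaviors=behaviors, seed=seed)


def run_labels(labels, frame_rate: float = 10.0) -> GroundTruthEthogram:
    """Wrap an explicit per-frame label array as a script."""
    return GroundTruthEthogram(frame_rate=frame_rate,
                               labels=np.asarray(labels, dtype=object),
                               bout_means_s={}, rhythm_params=None, seed=0)


@pytest.fixture(scope="session")
def short_video(default_appearance):
    """A 2-minute benchmark video with its script and ROI."""
    script = make_script(120.0, seed=7)
    roi = default_roi()
    video = render_video(script, default_appearance, roi, seed=8)
    return script, roi, video
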