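"""End-to-end orchestration: video -> features -> labels -> ethogram.

`run_detect` chains background modeling, segmentation, feature
extraction, kNN classification, 12/15 pruning, and five-behavior
ethogram assembly for one fly video.  `synthetic_training_set` renders
scripted videos and labels their feature vectors from the script,
standing in for the manually annotated training data of a real
deployment.  `run_rhythm` bundles the spectral analyses for a binned
series.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .background import build_backgrounds
from .behaviors import GROOMING, LOCOMOTION, REST, SHORT_REST, SLEEP, \
    AnalysisClock
from .classify import (DEFAULT_K, DEFAULT_MIN_GROOMING, DEFAULT_PRUNE_WINDOW,
                       KnnModel, TrainingSet, classify, prune_labels)
from .ethogram import (DEFAULT_BIN_MINUTES, DEFAULT_FEED_MIN_DURATION_S,
                       DEFAULT_SLEEP_THRESHOLD_MIN, Ethogram, build_ethogram,
                       estimate_body_length)
from .features import (DEFAULT_MIN_CD, extract_feature_series,
                       features_as_matrix, observe_frames)
from .rhythm import dominant_period, lomb_scargle
from .segmentation import DEFAULT_C0, DEFAULT_C1, TubeROI
from .synthetic import (FlyAppearance, default_roi, generate_ethogram_script,
                        render_video)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds with their standard defaults."""

    c0: int = DEFAULT_C0
    c1: int = DEFAULT_C1
    min_cd: float = DEFAULT_MIN_CD
    k: int = DEFAULT_K
    prune_window: int = DEFAULT_PRUNE_WINDOW
    min_grooming: int = DEFAULT_MIN_GROOMING
    sleep_threshold_min: float = DEFAULT_SLEEP_THRESHOLD_MIN
    feed_min_duration_s: float = DEFAULT_FEED_MIN_DURATION_S
    bin_minutes: float = DEFAULT_BIN_MINUTES
    background_interval_s: float = 1000.0
    native_rate: float = 10.0
    stride: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c0", "c1", "min_cd", "k", "prune_window",
                     "min_grooming", "sleep_threshold_min", "bin_minutes",
                     "background_interval_s", "native_rate", "stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    @property
    def clock(self) -> AnalysisClock:
        return AnalysisClock(native_rate=self.native_rate, stride=self.stride)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DetectionResult:
    """Outputs of the detection pipeline for one fly."""

    fly_id: str
    raw_labels: np.ndarray
    pruned_labels: np.ndarray
    ethogram: Ethogram
    features: np.ndarray
    centroids: np.ndarray
    body_length: float
    config: RunConfig


def run_detect(video: np.ndarray, roi: TubeROI, model: KnnModel,
               config: RunConfig | None = None) -> DetectionResult:
    """Classify one fly video into a five-behavior ethogram.

    The per-frame truth alphabet of the classifier is three-class; the
    feature series has one entry per analyzed frame pair, so labels are
    aligned to analyzed frames 1..n-1.
    """
    config = config or RunConfig()
    roi.validate_within(video.shape[1:])
    clock = config.clock
    backgrounds = build_backgrounds(video, config.native_rate,
                                    config.background_interval_s,
                                    c0=config.c0, seed=config.seed)
    observations = observe_frames(video, backgrounds, roi, clock,
                                  c0=config.c0, c1=config.c1)
    series = extract_feature_series(video, backgrounds, roi, clock,
                                    c0=config.c0, c1=config.c1,
                                    min_cd=config.min_cd)
    features = features_as_matrix(series)
    raw = classify(model, features)
    pruned = prune_labels(raw, window=config.prune_window,
                          min_grooming=config.min_grooming)
    centroids = np.array([o.centroid_axis for o in observations[1:]])
    body_length = estimate_body_length(observations, roi)
    eth = build_ethogram(pruned, centroids, roi.food_position, body_length,
                         clock=clock,
                         sleep_threshold_min=config.sleep_threshold_min,
                         feed_min_duration_s=config.feed_min_duration_s,
                         fly_id=roi.fly_id)
    return DetectionResult(fly_id=roi.fly_id, raw_labels=raw,
                           pruned_labels=pruned, ethogram=eth,
                           features=features, centroids=centroids,
                           body_length=body_length, config=config)


#: Script alphabet used for classifier benchmarks: the three classes the
#: kNN sees, with rest realized as (short) quiescence.
BENCHMARK_BEHAVIORS = (GROOMING, LOCOMOTION, SHORT_REST)

#: Bout means (s) for benchmark scripts: grooming/locomotion at the
#: field-typical event durations, rest kept short so that all three
#: classes are well represented in a 10-minute video.
BENCHMARK_BOUT_MEANS = {GROOMING: 13.8, LOCOMOTION: 26.4, SHORT_REST: 20.0}


def truth_for_features(script, clock: AnalysisClock) -> np.ndarray:
    """Three-class ground truth aligned to the feature series.

    Feature vector i describes the pair of analyzed frames (i, i+1) and
    is labeled with the script's behavior at the later frame; the
    short-rest/sleep script classes map to the classifier's 'rest'.
    """
    labels = script.analyzed_labels(clock)[1:].copy()
    labels[(labels == SHORT_REST) | (labels == SLEEP)] = REST
    return labels


def synthetic_training_set(seed: int = 1234, n_videos: int = 3,
                           duration_s: float = 120.0,
                           appearance: FlyAppearance | None = None,
                           config: RunConfig | None = None) -> TrainingSet:
    """Labeled feature vectors from scripted videos (training fixture).

    Stands in for a manually annotated training corpus: scripted
    grooming/locomotion/rest videos are rendered, features extracted by
    the standard pipeline, and each frame pair labeled from the script.
    Frame pairs that straddle a behavior transition are dropped (their
    features mix two behaviors, as a human annotator would skip them).
    """
    appearance = appearance or FlyAppearance()
    config = config or RunConfig()
    clock = config.clock
    samples, labels = [], []
    for v in range(n_videos):
        script = generate_ethogram_script(
            duration_s, frame_rate=config.native_rate,
            bout_means_s=BENCHMARK_BOUT_MEANS,
            behaviors=BENCHMARK_BEHAVIORS, seed=seed + 1000 * v)
        roi = default_roi()
        video = render_video(script, appearance, roi, seed=seed + 1000 * v + 1)
        backgrounds = build_backgrounds(video, config.native_rate,
                                        config.background_interval_s,
                                        c0=config.c0, seed=config.seed)
        series = extract_feature_series(video, backgrounds, roi, clock,
                                        c0=config.c0, c1=config.c1,
                                        min_cd=config.min_cd)
        feats = features_as_matrix(series)
        analyzed = script.analyzed_labels(clock)
        pair_truth = truth_for_features(script, clock)
        clean = analyzed[1:] == analyzed[:-1]  # drop transition pairs
        samples.append(feats[clean])
        labels.append(pair_truth[clean])
    return TrainingSet(samples=np.vstack(samples),
                       labels=np.concatenate(labels),
                       provenance=f"synthetic(seed={seed}, n={n_videos})")


def run_rhythm(values: np.ndarray, bin_minutes: float,
               band_h: tuple[float, float] = (16.0, 32.0)) -> dict:
    """Periodogram + dominant period summary for one binned series."""
    pg = lomb_scargle(values, bin_minutes)
    period, power, significant_at = dominant_period(pg, band_h)
    return {"periodogram": pg, "period_h": period, "peak_power": power,
            "significant_at": significant_at}
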