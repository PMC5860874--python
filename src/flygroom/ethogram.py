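"""Five-behavior ethogram assembly, binning, and bout statistics.

The classifier emits grooming/locomotion/rest labels.  Two derived
behaviors are overlaid:

* feeding — prolonged proximity to the food end of the tube (> 3 s at a
  distance of less than one body length), a proxy for feeding; feeding
  frames were initially classified as locomotion (the fly's centroid
  moves while it walks to the food), so feeding replaces only
  locomotion and short-rest frames, never grooming or sleep;
* sleep — a rest bout lasting at least 5 min, the standard fly-sleep
  definition; shorter quiescence is "short rest".

The result is one of five mutually exclusive behaviors per analyzed
frame; wake is their union minus sleep.  Binned fraction-of-time series
(default 30 min bins) feed the rhythm analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviors import (ETHOGRAM_CLASSES, FEEDING, LOCOMOTION, REST,
                        SHORT_REST, SLEEP, AnalysisClock)

DEFAULT_SLEEP_THRESHOLD_MIN = 5.0
DEFAULT_FEED_MIN_DURATION_S = 3.0
DEFAULT_BIN_MINUTES = 30.0


@dataclass
class Ethogram:
    """Per-analyzed-frame five-class behavior record for one fly."""

    labels: np.ndarray
    clock: AnalysisClock = field(default_factory=AnalysisClock)
    fly_id: str = "fly0"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(ETHOGRAM_CLASSES)
        if bad:
            raise ValueError(f"labels outside the five-class alphabet: {bad}")

    @property
    def wake(self) -> np.ndarray:
        """Per-frame wake flag: the complement of sleep."""
        return self.labels != SLEEP


@dataclass
class BinnedSeries:
    """Fraction-of-time-per-behavior series on a fixed bin grid."""

    bin_minutes: float
    fractions: pd.DataFrame  # one column per behavior, one row per bin
    lights: np.ndarray | None = None  # True while lights are on
    t0_min: float = 0.0  # zeitgeber time of the first bin start (minutes)


def detect_feeding(centroid_series: np.ndarray, food_position: float,
                   body_length: float, clock: AnalysisClock | None = None,
                   min_duration_s: float = DEFAULT_FEED_MIN_DURATION_S
                   ) -> list[tuple[int, int]]:
    """Half-open analyzed-frame intervals of prolonged food proximity.

    An interval qualifies as feeding when the centroid stays within one
    body length of the food position for strictly more than
    ``min_duration_s`` seconds.
    """
    if body_length <= 0:
        raise ValueError("body_length must be positive")
    clock = clock or AnalysisClock()
    near = np.abs(np.asarray(centroid_series, dtype=float) - food_position) \
        < body_length
    intervals = []
    for start, stop in _runs(near):
        if (stop - start) / clock.analysis_rate > min_duration_s:
            intervals.append((start, stop))
    return intervals


def classify_rest_bouts(pruned_labels: np.ndarray,
                        clock: AnalysisClock | None = None,
                        sleep_threshold_min: float = DEFAULT_SLEEP_THRESHOLD_MIN
                        ) -> list[tuple[int, int, str]]:
    """Tag maximal rest runs as sleep (>= 5 min) or short rest (< 5 min)."""
    clock = clock or AnalysisClock()
    labels = np.asarray(pruned_labels, dtype=object)
    out = []
    for start, stop in _runs(labels == REST):
        duration_s = (stop - start) / clock.analysis_rate
        kind = SLEEP if duration_s >= sleep_threshold_min * 60.0 else SHORT_REST
        out.append((start, stop, kind))
    return out


def assemble_ethogram(pruned_labels: np.ndarray,
                      feeding_intervals: list[tuple[int, int]],
                      rest_bouts: list[tuple[int, int, str]],
                      clock: AnalysisClock | None = None,
                      fly_id: str = "fly0") -> Ethogram:
    """Merge classifier output with feeding and sleep overlays.

    Per-frame precedence: sleep > feeding > pruned label.  Feeding
    replaces only locomotion and short-rest frames — grooming labels are
    preserved and sleep, being defined purely by quiescence length,
    outranks food proximity.
    """
    clock = clock or AnalysisClock()
    labels = np.asarray(pruned_labels, dtype=object).copy()
    for start, stop, kind in rest_bouts:
        labels[start:stop] = kind
    for start, stop in feeding_intervals:
        seg = labels[start:stop]
        seg[(seg == LOCOMOTION) | (seg == SHORT_REST)] = FEEDING
        labels[start:stop] = seg
    if np.any(labels == REST):
        raise ValueError("rest bouts do not cover all rest frames")
    return Ethogram(labels=labels, clock=clock, fly_id=fly_id)


def build_ethogram(pruned_labels: np.ndarray, centroid_series: np.ndarray,
                   food_position: float, body_length: float,
                   clock: AnalysisClock | None = None,
                   sleep_threshold_min: float = DEFAULT_SLEEP_THRESHOLD_MIN,
                   feed_min_duration_s: float = DEFAULT_FEED_MIN_DURATION_S,
                   fly_id: str = "fly0") -> Ethogram:
    """Convenience wrapper: feeding detection + sleep tagging + assembly."""
    clock = clock or AnalysisClock()
    feeding = detect_feeding(centroid_series, food_position, body_length,
                             clock=clock, min_duration_s=feed_min_duration_s)
    rest_bouts = classify_rest_bouts(pruned_labels, clock=clock,
                                     sleep_threshold_min=sleep_threshold_min)
    return assemble_ethogram(pruned_labels, feeding, rest_bouts,
                             clock=clock, fly_id=fly_id)


def bin_fractions(ethogram: Ethogram,
                  bin_minutes: float = DEFAULT_BIN_MINUTES,
                  lights_period_h: float | None = 24.0,
                  lights_on_frac: float = 0.5,
                  t0_min: float = 0.0) -> BinnedSeries:
    """Fraction of analyzed frames spent in each behavior per time bin.

    The final partial bin is normalized by its own frame count.  Lights
    annotation follows an LD cycle of ``lights_period_h`` with the first
    ``lights_on_frac`` of each cycle lit; pass ``lights_period_h=None``
    for constant darkness.
    """
    if len(ethogram.labels) == 0:
        raise ValueError("ethogram is empty")
    frames_per_bin = int(round(bin_minutes * 60.0 * ethogram.clock.analysis_rate))
    n = len(ethogram.labels)
    n_bins = -(-n // frames_per_bin)
    rows = []
    for b in range(n_bins):
        chunk = ethogram.labels[b * frames_per_bin:(b + 1) * frames_per_bin]
        rows.append({cls: float(np.mean(chunk == cls))
                     for cls in ETHOGRAM_CLASSES})
    fractions = pd.DataFrame(rows, columns=list(ETHOGRAM_CLASSES))
    if lights_period_h is None:
        lights = np.zeros(n_bins, dtype=bool)
    else:
        centers_h = (t0_min + (np.arange(n_bins) + 0.5) * bin_minutes) / 60.0
        lights = (centers_h % lights_period_h) < lights_on_frac * lights_period_h
    return BinnedSeries(bin_minutes=bin_minutes, fractions=fractions,
                        lights=lights, t0_min=t0_min)


def bout_statistics(ethogram: Ethogram) -> pd.DataFrame:
    """Per-bout table: behavior, start frame, duration (s), inter-event gap.

    ``gap_before_s`` is the pause since the end of the previous bout of
    the same behavior (NaN for the first bout of each behavior).
    """
    rate = ethogram.clock.analysis_rate
    records = []
    last_end: dict[str, int] = {}
    for start, stop, cls in _label_runs(ethogram.labels):
        gap = (start - last_end[cls]) / rate if cls in last_end else float("nan")
        records.append({"behavior": cls, "start_frame": start,
                        "duration_s": (stop - start) / rate,
                        "gap_before_s": gap})
        last_end[cls] = stop
    return pd.DataFrame(records,
                        columns=["behavior", "start_frame", "duration_s",
                                 "gap_before_s"])


def bout_summary(bouts: pd.DataFrame) -> pd.DataFrame:
    """Per-behavior mean bout duration and longest inter-event pause."""
    rows = []
    for cls in ETHOGRAM_CLASSES:
        sub = bouts[bouts["behavior"] == cls]
        if len(sub) == 0:
            rows.append({"behavior": cls, "n_bouts": 0,
                         "mean_duration_s": float("nan"),
                         "longest_pause_s": float("nan")})
        else:
            gaps = sub["gap_before_s"].dropna()
            rows.append({"behavior": cls, "n_bouts": len(sub),
                         "mean_duration_s": float(sub["duration_s"].mean()),
                         "longest_pause_s": float(gaps.max()) if len(gaps)
                         else float("nan")})
    return pd.DataFrame(rows)


def estimate_body_length(observations, roi) -> float:
    """Median per-frame fly extent along the tube axis over detected frames."""
    extents = []
    for obs in observations:
        if obs.detected and obs.area:
            proj = roi.project(obs.pixels[:, 0].astype(float),
                               obs.pixels[:, 1].astype(float))
            extents.append(proj.max() - proj.min() + 1.0)
    if not extents:
        raise ValueError("no detected frames to estimate body length from")
    return float(np.median(extents))


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) intervals of consecutive True values."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) == 0:
        return []
    edges = np.flatnonzero(np.diff(flags.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [len(flags)]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])
            if flags[a]]


def _label_runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of identical labels as (start, stop, label)."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1])
    bounds = np.concatenate([[0], change + 1, [len(labels)]])
    return [(int(a), int(b), labels[a]) for a, b in zip(bounds[:-1], bounds[1:])]
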