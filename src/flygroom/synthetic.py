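"""Synthetic ground truth: ethogram scripts, fly videos, rhythmic series.

Real recordings are long infrared videos of single flies in glass
tubes.  This module generates stand-ins with known ground truth so that
every downstream stage (background modeling, segmentation, features,
classification, ethogram assembly, rhythm analysis) can be validated
without recorded data:

* :func:`generate_ethogram_script` draws an alternating-bout behavior
  script (exponential bout lengths around field-typical means, with
  optional circadian modulation of behavior choice);
* :func:`render_video` draws the script as an 8-bit grayscale frame
  stack of a two-tone fly (dark core ~40, lighter periphery ~90, area
  ~300 px on a ~120 background) with behavior-faithful motion and
  additive Gaussian sensor noise;
* :func:`generate_rhythmic_series` produces binned activity series with
  a controlled circadian component for the spectral stages.

The renderer is deliberately schematic: grooming is emulated by
re-drawing a random 10-40% of periphery pixels at adjacent positions
each frame (periphery churn with a near-static centroid, the PM >> CM
signature of real grooming), not by modeling limbs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviors import (ETHOGRAM_CLASSES, FEEDING, GROOMING, LOCOMOTION,
                        SHORT_REST, SLEEP, AnalysisClock)
from .ethogram import BinnedSeries
from .rhythm import two_peak_template
from .segmentation import TubeROI

#: Mean bout durations (seconds).  Grooming and locomotion follow the
#: ~0.23 min and ~0.44 min event means typical of single-fly tube
#: recordings; the others are generic field-plausible choices.
DEFAULT_BOUT_MEANS_S = {
    GROOMING: 13.8,
    LOCOMOTION: 26.4,
    FEEDING: 10.0,
    SHORT_REST: 45.0,
    SLEEP: 1200.0,
}

#: Relative frequency weights for choosing the next bout's behavior.
DEFAULT_BOUT_WEIGHTS = {
    GROOMING: 1.0,
    LOCOMOTION: 1.0,
    FEEDING: 0.3,
    SHORT_REST: 1.0,
    SLEEP: 0.4,
}

SLEEP_MIN_S = 300.0  # sleep bouts are >= 5 min by definition


@dataclass(frozen=True)
class RhythmParams:
    """Circadian modulation of behavior choice in scripted ethograms."""

    period_h: float = 24.0
    peak_phases_h: tuple[float, float] = (0.0, 12.0)
    depth: float = 0.5  # 0 = no modulation, 1 = full on/off swing


@dataclass(frozen=True)
class FlyAppearance:
    """Grayscale appearance of the rendered fly."""

    area: int = 300
    core_gray: int = 40
    periphery_gray: int = 90
    background_gray: int = 120
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (self.core_gray < self.periphery_gray < self.background_gray):
            raise ValueError(
                "appearance must satisfy core < periphery < background "
                "(the fly is darker than its surroundings)")
        if self.area <= 25:
            raise ValueError("fly area must exceed the artifact threshold C1")


@dataclass
class GroundTruthEthogram:
    """Scripted per-frame behavior labels at the native frame rate."""

    frame_rate: float
    labels: np.ndarray
    bout_means_s: dict[str, float]
    rhythm_params: RhythmParams | None
    seed: int

    @property
    def duration_s(self) -> float:
        return len(self.labels) / self.frame_rate

    def analyzed_labels(self, clock: AnalysisClock | None = None) -> np.ndarray:
        """Ground-truth labels subsampled to the analyzed frames."""
        clock = clock or AnalysisClock(native_rate=self.frame_rate)
        return self.labels[::clock.stride]

    def fractions(self) -> dict[str, float]:
        return {cls: float(np.mean(self.labels == cls))
                for cls in ETHOGRAM_CLASSES}


def _activity_profile(t_h: np.ndarray | float, params: RhythmParams) -> np.ndarray:
    """Two-peak daily activity profile in [0, 1] (morning + evening bumps)."""
    t_h = np.asarray(t_h, dtype=float)
    width = params.period_h / 6.0  # half-width of each bump
    prof = np.zeros_like(t_h)
    for phase in params.peak_phases_h:
        d = np.abs((t_h - phase + params.period_h / 2) % params.period_h
                   - params.period_h / 2)
        bump = np.where(d < width, np.cos(np.pi * d / (2 * width)) ** 2, 0.0)
        prof = np.maximum(prof, bump)
    return prof


def _draw_bout_duration(behavior: str, mean_s: float,
                        rng: np.random.Generator, min_s: float) -> float:
    """Exponential bout length with the sleep/short-rest constraints."""
    if behavior == SLEEP:
        excess = max(mean_s - SLEEP_MIN_S, 1.0)
        return SLEEP_MIN_S + rng.exponential(excess)
    if behavior == SHORT_REST:
        # inverse-CDF draw from the exponential truncated below 5 min
        u = rng.uniform()
        cap = 1.0 - np.exp(-SLEEP_MIN_S / mean_s)
        return max(min_s, -mean_s * np.log(1.0 - u * cap))
    return max(min_s, rng.exponential(mean_s))


def generate_ethogram_script(duration_s: float, frame_rate: float = 10.0,
                             bout_means_s: dict[str, float] | None = None,
                             rhythm_params: RhythmParams | None = None,
                             seed: int = 0,
                             behaviors: tuple[str, ...] | None = None,
                             weights: dict[str, float] | None = None
                             ) -> GroundTruthEthogram:
    """Draw an alternating-bout behavior script.

    Bout lengths are exponential around per-behavior means (floored at
    one analyzed-frame period; sleep shifted to >= 5 min, short rest
    truncated below 5 min).  The next bout's behavior is drawn with
    fixed weights, excluding the current behavior; with
    ``rhythm_params`` the weights of active behaviors follow a two-peak
    daily profile while rest/sleep weights follow its complement.
    Deterministic for a fixed seed.
    """
    if duration_s <= 0 or frame_rate <= 0:
        raise ValueError("duration_s and frame_rate must be positive")
    means = dict(DEFAULT_BOUT_MEANS_S)
    means.update(bout_means_s or {})
    behaviors = tuple(behaviors or ETHOGRAM_CLASSES)
    weights = {**DEFAULT_BOUT_WEIGHTS, **(weights or {})}
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    min_bout_s = 2.0 / frame_rate  # one analyzed-frame pair at 5 Hz
    labels = np.empty(n_frames, dtype=object)
    t = 0
    current: str | None = None
    active = {GROOMING, LOCOMOTION, FEEDING}
    while t < n_frames:
        options = [b for b in behaviors if b != current]
        if not options:  # single-behavior script
            options = list(behaviors)
        w = np.array([weights.get(b, 1.0) for b in options], dtype=float)
        if rhythm_params is not None:
            prof = float(_activity_profile(t / frame_rate / 3600.0,
                                           rhythm_params))
            d = rhythm_params.depth
            for i, b in enumerate(options):
                w[i] *= (1 - d) + 2 * d * (prof if b in active else 1 - prof)
        current = options[int(rng.choice(len(options), p=w / w.sum()))]
        dur_s = _draw_bout_duration(current, means[current], rng, min_bout_s)
        n = max(int(round(dur_s * frame_rate)), int(round(min_bout_s * frame_rate)))
        if current == SHORT_REST:
            n = min(n, int(SLEEP_MIN_S * frame_rate) - 1)
        elif current == SLEEP:
            n = max(n, int(np.ceil(SLEEP_MIN_S * frame_rate)))
        labels[t:t + n] = current
        t += n
    return GroundTruthEthogram(frame_rate=frame_rate, labels=labels,
                               bout_means_s=means, rhythm_params=rhythm_params,
                               seed=seed)


# ---------------------------------------------------------------------------
# Video rendering
# ---------------------------------------------------------------------------

def _fly_template(area: int, aspect: float = 1.5
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Core and periphery pixel offsets of an elliptical two-tone fly.

    Returns ``(core_offsets, periphery_offsets)`` as (n, 2) arrays of
    (drow, dcol) relative to the body center.  The core is the inner
    half of the pixels by elliptical radius, mimicking the darker
    thorax/abdomen inside a lighter periphery of legs, head and wings.
    """
    a = np.sqrt(area * aspect / np.pi)  # semi-axis along the tube (cols)
    b = a / aspect
    r_max = int(np.ceil(a)) + 1
    dr, dc = np.mgrid[-r_max:r_max + 1, -r_max:r_max + 1]
    radius = np.sqrt((dc / a) ** 2 + (dr / b) ** 2)
    order = np.argsort(radius.ravel(), kind="stable")[:area]
    offsets = np.column_stack([dr.ravel()[order], dc.ravel()[order]])
    n_core = area // 2
    return offsets[:n_core].copy(), offsets[n_core:].copy()


def _occupancy(offsets: np.ndarray) -> tuple[np.ndarray, int]:
    pad = int(np.abs(offsets).max()) + 2
    grid = np.zeros((2 * pad + 1, 2 * pad + 1), dtype=bool)
    grid[offsets[:, 0] + pad, offsets[:, 1] + pad] = True
    return grid, pad


_JITTER_SHIFTS = np.array([[0, 1], [0, -1], [1, 0], [-1, 0]])


def render_video(script: GroundTruthEthogram, appearance: FlyAppearance,
                 roi: TubeROI, seed: int = 0,
                 frame_shape: tuple[int, int] | None = None,
                 background_drift_per_s: float = 0.0,
                 locomotion_speed_px: int = 1,
                 jitter_fraction: tuple[float, float] = (0.1, 0.4)
                 ) -> np.ndarray:
    """Render a script as an (n, h, w) uint8 grayscale frame stack.

    Behavior-faithful motion: rest/sleep/short rest frames repeat the
    fly pixels exactly (noise aside); grooming re-draws a random
    10-40% of periphery pixels at adjacent free positions each frame
    while the core stays put (centroid shift well under 0.5 px);
    locomotion translates the whole body along the tube axis by
    ``locomotion_speed_px`` per native frame (>= 1 px per analyzed
    pair); feeding parks the fly with its centroid within one body
    length of the food coordinate.  ``background_drift_per_s`` adds a
    slow uniform brightening to exercise background refresh.
    """
    if frame_shape is None:
        frame_shape = (roi.row_stop, roi.col_stop)
    roi.validate_within(frame_shape)
    rng = np.random.default_rng(seed)
    core_off, peri_off = _fly_template(appearance.area)
    occ, pad = _occupancy(np.vstack([core_off, peri_off]))
    half_len = int(np.abs(np.vstack([core_off, peri_off])[:, 1]).max())
    half_ht = int(np.abs(np.vstack([core_off, peri_off])[:, 0]).max())
    body_length = 2 * half_len + 1

    row_c = (roi.row_start + roi.row_stop) // 2
    if not (roi.row_start + half_ht < row_c < roi.row_stop - half_ht):
        raise ValueError("ROI too short across the tube for the fly body")
    col_min = roi.col_start + half_len + 2
    col_max = roi.col_stop - half_len - 3
    if col_max - col_min < body_length:
        raise ValueError("ROI too narrow along the tube for fly movement")
    feed_col = int(np.clip(round(roi.food_position), col_min, col_max))

    n_frames = len(script.labels)
    frames = np.empty((n_frames, *frame_shape), dtype=np.uint8)
    col = (col_min + col_max) // 2
    direction = 1
    n_peri = len(peri_off)
    lo_f, hi_f = jitter_fraction

    for i, label in enumerate(script.labels):
        if label == LOCOMOTION:
            col += direction * locomotion_speed_px
            if col >= col_max or col <= col_min:
                col = int(np.clip(col, col_min, col_max))
                direction = -direction
        elif label == FEEDING:
            col = feed_col
        peri = peri_off
        if label == GROOMING:
            k = int(round(rng.uniform(lo_f, hi_f) * n_peri))
            if k:
                sel = rng.choice(n_peri, size=k, replace=False)
                shifts = _JITTER_SHIFTS[rng.integers(0, 4, size=k)]
                targets = peri_off[sel] + shifts
                free = ~occ[targets[:, 0] + pad, targets[:, 1] + pad]
                # drop duplicate targets so the pixel count is preserved
                _, first = np.unique(targets, axis=0, return_index=True)
                keep = np.zeros(k, dtype=bool)
                keep[first] = True
                ok = free & keep
                peri = peri_off.copy()
                peri[sel[ok]] = targets[ok]

        base = appearance.background_gray + background_drift_per_s * \
            (i / script.frame_rate)
        canvas = np.full(frame_shape, base, dtype=float)
        canvas[core_off[:, 0] + row_c, core_off[:, 1] + col] = appearance.core_gray
        canvas[peri[:, 0] + row_c, peri[:, 1] + col] = appearance.periphery_gray
        if appearance.noise_sd > 0:
            canvas += rng.normal(0.0, appearance.noise_sd, size=frame_shape)
        frames[i] = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return frames


def default_roi(height: int = 64, width: int = 420,
                fly_id: str = "fly0") -> TubeROI:
    """A single-tube ROI spanning a whole synthetic frame, food at the left."""
    return TubeROI(row_start=0, row_stop=height, col_start=0, col_stop=width,
                   axis=(0.0, 1.0), food_position=24.0, fly_id=fly_id)


# ---------------------------------------------------------------------------
# Rhythmic binned series
# ---------------------------------------------------------------------------

def generate_rhythmic_series(period_h: float, days: float,
                             bin_min: float = 30.0, amplitude: float = 0.15,
                             noise_sd: float = 0.05, seed: int = 0,
                             baseline: float = 0.3,
                             shape: str = "sinusoid") -> BinnedSeries:
    """Nonnegative binned activity with a controlled circadian component.

    ``shape`` is ``"sinusoid"`` or ``"two_peak"`` (morning/evening
    template).  Values are clipped to [0, 1] like behavior fractions.
    Rejects bins too coarse to resolve the period (Nyquist).
    """
    if period_h <= 2.0 * bin_min / 60.0:
        raise ValueError("bin size too coarse for the requested period")
    n_bins = int(round(days * 24.0 * 60.0 / bin_min))
    t_h = np.arange(n_bins) * bin_min / 60.0
    if shape == "sinusoid":
        signal = amplitude * np.cos(2.0 * np.pi * t_h / period_h)
    elif shape == "two_peak":
        # asymmetric morning/evening peaks so the fundamental (one cycle
        # per period) dominates the half-period harmonic
        template = two_peak_template(
            t_h, np.array([0.5, 0.5, 0.5, 0.5, period_h, 3.0, 6.0, 1.0, 0.5]))
        template = template - template.mean()
        peak = np.max(np.abs(template)) or 1.0
        signal = amplitude * template / peak
    else:
        raise ValueError("shape must be 'sinusoid' or 'two_peak'")
    rng = np.random.default_rng(seed)
    values = baseline + signal + rng.normal(0.0, noise_sd, size=n_bins)
    values = np.clip(values, 0.0, 1.0)
    fractions = pd.DataFrame({"activity": values})
    return BinnedSeries(bin_minutes=bin_min, fractions=fractions,
                        lights=None, t0_min=0.0)
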