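"""Movement features: periphery movement, core movement, centroid displacement.

For each pair of consecutive analyzed frames (5 Hz on a 10 Hz video) the
pipeline computes three per-fly features:

* PM — number of non-overlapping periphery pixels between the frames
  (symmetric difference of the periphery pixel sets);
* CM — the same for the core;
* CD — absolute centroid displacement projected on the tube's long
  axis, with sub-threshold displacements (< 0.5 px) zeroed as noise.

PM and CM are areas while CD is a length, so PM and CM enter the
feature space as square roots; all three are divided by the scale
parameter SP = sqrt(fly area), making the features dimensionless and
comparable across flies of different sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behaviors import AnalysisClock
from .background import (BackgroundFrame, background_for_frame,
                         hold_last_position)
from .segmentation import (DEFAULT_C0, DEFAULT_C1, TubeROI, extract_foreground,
                           extract_foreground_hysteresis, observe_fly,
                           remove_small_objects, split_core_periphery)

#: Minimum centroid displacement (pixels) accepted as true movement;
#: smaller displacements are imaging noise (excludes >99.99% of false ones).
DEFAULT_MIN_CD = 0.5


@dataclass(frozen=True)
class FeatureVector:
    """Normalized (and raw) movement features for one analyzed frame pair.

    ``frame_index`` is the analyzed index of the *later* frame of the pair.
    """

    frame_index: int
    nPM: float
    nCM: float
    nCD: float
    raw_PM: int = 0
    raw_CM: int = 0
    raw_CD: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.nPM, self.nCM, self.nCD])


def compute_part_movement(prev_part_pixels: np.ndarray,
                          curr_part_pixels: np.ndarray) -> int:
    """Count of non-overlapping pixels: |symmetric difference| of two sets.

    Pixel sets are (n, 2) integer arrays of (row, col) coordinates in a
    common frame of reference.
    """
    prev = {(int(r), int(c)) for r, c in np.asarray(prev_part_pixels).reshape(-1, 2)}
    curr = {(int(r), int(c)) for r, c in np.asarray(curr_part_pixels).reshape(-1, 2)}
    return len(prev ^ curr)


def _mask_movement(prev_mask: np.ndarray, curr_mask: np.ndarray) -> int:
    """Symmetric-difference count on boolean masks (fast path)."""
    return int(np.count_nonzero(prev_mask ^ curr_mask))


def compute_cd(prev_centroid_axis: float, curr_centroid_axis: float,
               min_cd: float = DEFAULT_MIN_CD) -> float:
    """Axis-projected centroid displacement with the noise floor applied.

    Displacements smaller than ``min_cd`` are ignored (returned as 0);
    a displacement of exactly ``min_cd`` is retained.
    """
    d = abs(curr_centroid_axis - prev_centroid_axis)
    return 0.0 if d < min_cd else float(d)


def normalize_features(raw_pm: int, raw_cm: int, raw_cd: float, area: int,
                       frame_index: int = 0,
                       sqrt_areas: bool = True) -> FeatureVector:
    """Scale raw features by SP = sqrt(area) into a dimensionless vector.

    With ``sqrt_areas`` (the default) the area-like features PM and CM
    are square-rooted first so that all three features share the
    dimension of length before division by SP.  The alternative reading
    (PM/SP without the square root) is kept as a switch.
    """
    if area <= 0:
        raise ValueError("fly area must be positive for normalization")
    sp = float(np.sqrt(area))
    if sqrt_areas:
        npm, ncm = np.sqrt(raw_pm) / sp, np.sqrt(raw_cm) / sp
    else:
        npm, ncm = raw_pm / sp, raw_cm / sp
    return FeatureVector(frame_index=frame_index,
                         nPM=float(npm), nCM=float(ncm), nCD=float(raw_cd) / sp,
                         raw_PM=int(raw_pm), raw_CM=int(raw_cm),
                         raw_CD=float(raw_cd))


def _part_mask(pixels: np.ndarray | None, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if pixels is not None and len(pixels):
        mask[pixels[:, 0], pixels[:, 1]] = True
    return mask


def observe_frames(video: np.ndarray, backgrounds: list[BackgroundFrame],
                   roi: TubeROI, clock: AnalysisClock,
                   c0: int = DEFAULT_C0, c1: int = DEFAULT_C1,
                   hysteresis: bool = True) -> list:
    """Segment the fly on every analyzed frame and fill detection gaps."""
    observations = []
    for analyzed_index in range(clock.n_analyzed(len(video))):
        native = clock.native_index(analyzed_index)
        frame = video[native]
        bg = background_for_frame(backgrounds, native)
        if hysteresis:
            fg = extract_foreground_hysteresis(frame, bg, c0=c0)
        else:
            fg = extract_foreground(frame, bg, c0=c0)
        mask = remove_small_objects(fg, c1=c1)
        obs = observe_fly(mask, frame, roi, frame_index=analyzed_index)
        if obs.detected:
            split_core_periphery(obs)
        observations.append(obs)
    return hold_last_position(observations)


def extract_feature_series(video: np.ndarray,
                           backgrounds: list[BackgroundFrame],
                           roi: TubeROI,
                           clock: AnalysisClock | None = None,
                           c0: int = DEFAULT_C0, c1: int = DEFAULT_C1,
                           min_cd: float = DEFAULT_MIN_CD,
                           sqrt_areas: bool = True) -> list[FeatureVector]:
    """Full feature extraction for one fly: one vector per analyzed pair.

    Returns ``n_analyzed - 1`` feature vectors; vector ``i`` describes
    the movement between analyzed frames ``i`` and ``i + 1`` and is
    stamped with the later frame's index.  Raises
    :class:`~flygroom.background.FlyNeverDetectedError` if the fly is
    absent from the whole video.
    """
    clock = clock or AnalysisClock()
    observations = observe_frames(video, backgrounds, roi, clock, c0=c0, c1=c1)
    shape = video.shape[1:]
    series: list[FeatureVector] = []
    prev = observations[0]
    prev_core = _part_mask(prev.core_pixels if prev.detected else None, shape)
    prev_peri = _part_mask(prev.periphery_pixels if prev.detected else None, shape)
    for curr in observations[1:]:
        curr_core = _part_mask(curr.core_pixels if curr.detected else None, shape)
        curr_peri = _part_mask(curr.periphery_pixels if curr.detected else None, shape)
        raw_pm = _mask_movement(prev_peri, curr_peri)
        raw_cm = _mask_movement(prev_core, curr_core)
        if prev.detected and curr.detected:
            raw_cd = compute_cd(prev.centroid_axis, curr.centroid_axis, min_cd)
        else:  # leading undetected stretch: no displacement evidence
            raw_cd = 0.0
        area = curr.area if curr.detected else prev.area
        if area > 0:
            series.append(normalize_features(raw_pm, raw_cm, raw_cd, area,
                                             frame_index=curr.frame_index,
                                             sqrt_areas=sqrt_areas))
        else:
            series.append(FeatureVector(frame_index=curr.frame_index,
                                        nPM=0.0, nCM=0.0, nCD=0.0))
        prev, prev_core, prev_peri = curr, curr_core, curr_peri
    return series


def features_as_matrix(series: list[FeatureVector]) -> np.ndarray:
    """Stack feature vectors into an (n, 3) array of (nPM, nCM, nCD)."""
    return np.array([[f.nPM, f.nCM, f.nCD] for f in series]).reshape(-1, 3)
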