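"""Fly-free background construction and refresh scheduling.

The background (reference) frame is built by comparing one randomly
chosen template frame against seven randomly chosen contrast frames and
erasing every dark moving object from the template: wherever the
template pixel is darker than the contrast pixel by more than C0, the
(brighter) contrast value replaces it.  Because a fly is always darker
than its surroundings, this removes the fly provided it moved between
the template and at least one contrast frame.  The background is
regenerated every 1000 s to track slow changes in the tube (food level,
debris).  A fly that never moves within an interval is not erased and
hence not detected; those gaps are filled by holding the last detected
position.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import DEFAULT_C0, FlyObservation

#: Seconds between background regenerations.
DEFAULT_REFRESH_INTERVAL_S = 1000.0
#: Number of contrast frames compared against the template.
N_CONTRAST_FRAMES = 7


@dataclass(frozen=True)
class BackgroundFrame:
    """A background image valid over a half-open native-frame interval."""

    image: np.ndarray
    valid_from_frame: int
    valid_to_frame: int
    template_frame_index: int
    contrast_frame_indices: tuple[int, ...]


def build_background(template_frame: np.ndarray,
                     contrast_frames: list[np.ndarray] | np.ndarray,
                     c0: int = DEFAULT_C0) -> np.ndarray:
    """Erase dark moving objects from ``template_frame``.

    For each contrast frame in turn, every template pixel darker than
    the corresponding contrast pixel by more than ``c0`` is replaced by
    the contrast pixel.  The rule is one-sided: a dark object present
    only in a contrast frame is never imported into the template.  The
    result is (up to C0) the per-pixel maximum over the eight frames.
    """
    contrast_frames = list(np.asarray(f) for f in contrast_frames)
    if len(contrast_frames) < 1:
        raise ValueError("at least one contrast frame is required")
    out = np.asarray(template_frame).astype(np.int16)
    for contrast in contrast_frames:
        if contrast.shape != out.shape:
            raise ValueError("contrast frame shape differs from template")
        c = contrast.astype(np.int16)
        replace = (c - out) > c0
        out[replace] = c[replace]
    return out.astype(template_frame.dtype)


def refresh_schedule(n_frames: int, frame_rate: float,
                     interval_s: float = DEFAULT_REFRESH_INTERVAL_S,
                     seed: int = 0) -> list[dict]:
    """Plan the background intervals and their random frame draws.

    Returns one record per interval with keys ``start``, ``stop``
    (half-open native-frame bounds), ``template`` and ``contrasts``
    (frame indices drawn uniformly within the interval).  Consecutive
    intervals tile the video; the last may be shorter.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    interval_frames = max(1, int(round(interval_s * frame_rate)))
    rng = np.random.default_rng(seed)
    schedule = []
    start = 0
    while start < n_frames:
        stop = min(start + interval_frames, n_frames)
        pool = np.arange(start, stop)
        template = int(rng.choice(pool))
        contrasts = tuple(int(i) for i in rng.choice(pool, size=N_CONTRAST_FRAMES))
        schedule.append({"start": start, "stop": stop,
                         "template": template, "contrasts": contrasts})
        start = stop
    return schedule


def build_backgrounds(video: np.ndarray, frame_rate: float,
                      interval_s: float = DEFAULT_REFRESH_INTERVAL_S,
                      c0: int = DEFAULT_C0, seed: int = 0,
                      denoise: bool = True) -> list[BackgroundFrame]:
    """Build one background per refresh interval of ``video`` (n, h, w).

    With ``denoise`` (the default) the finished background is smoothed
    with a 3x3 median filter.  The background is a single (fly-erased)
    sensor frame, so its pixel noise is frozen for the whole interval;
    without smoothing, foreground pixels whose contrast to the
    background sits near C0 flicker in and out of the silhouette on
    every frame, inflating the movement features of a resting fly.
    """
    from scipy.ndimage import median_filter

    schedule = refresh_schedule(len(video), frame_rate, interval_s, seed=seed)
    backgrounds = []
    for rec in schedule:
        image = build_background(video[rec["template"]],
                                 [video[i] for i in rec["contrasts"]], c0=c0)
        if denoise:
            image = median_filter(image, size=3)
        backgrounds.append(BackgroundFrame(
            image=image, valid_from_frame=rec["start"], valid_to_frame=rec["stop"],
            template_frame_index=rec["template"],
            contrast_frame_indices=rec["contrasts"]))
    return backgrounds


def background_for_frame(backgrounds: list[BackgroundFrame],
                         frame_index: int) -> np.ndarray:
    for bg in backgrounds:
        if bg.valid_from_frame <= frame_index < bg.valid_to_frame:
            return bg.image
    raise ValueError(f"no background covers frame {frame_index}")


class FlyNeverDetectedError(RuntimeError):
    """Raised when a fly is absent from every analyzed frame."""


def hold_last_position(observations: list[FlyObservation]) -> list[FlyObservation]:
    """Fill detection gaps with the most recent detected observation.

    A fly immobile for longer than the refresh interval is absorbed into
    the background and disappears from the foreground; it is then
    considered stationary at its last detected position.  Frames in a
    gap inherit the full observation (pixels, grays, centroid) of the
    last detected frame, re-stamped with their own frame index.  A
    leading gap (before any detection) stays undetected; a fly never
    detected at all raises :class:`FlyNeverDetectedError`.
    """
    if not any(o.detected for o in observations):
        raise FlyNeverDetectedError("fly was never detected in any analyzed frame")
    filled: list[FlyObservation] = []
    last: FlyObservation | None = None
    for obs in observations:
        if obs.detected:
            last = obs
            filled.append(obs)
        elif last is None:
            filled.append(obs)
        else:
            filled.append(FlyObservation(
                frame_index=obs.frame_index, detected=True,
                pixels=last.pixels, grays=last.grays,
                centroid_axis=last.centroid_axis,
                core_pixels=last.core_pixels,
                periphery_pixels=last.periphery_pixels))
    return filled
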