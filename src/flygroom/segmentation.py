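"""Fly silhouette extraction from background-subtracted frames.

A fly is always darker than its surroundings under infrared back-light,
so foreground pixels are those where ``background - frame`` exceeds the
grayscale threshold C0.  Small connected components (noise artifacts)
are erased with an area threshold C1, the largest remaining blob inside
each tube region of interest is taken as the fly, and its body is split
at the median grayscale value into a darker core and a lighter
periphery of (near) equal pixel counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

#: Grayscale-difference threshold: changes of C0 or less are treated as
#: sensor noise (rules out >99.99% of fluctuations in the reference setup).
DEFAULT_C0 = 10
#: Minimum connected-component area (pixels); smaller blobs are artifacts.
DEFAULT_C1 = 25


@dataclass(frozen=True)
class TubeROI:
    """Rectangular region of interest holding a single fly tube.

    The rectangle is 0-based and half-open: rows ``[row_start, row_stop)``,
    columns ``[col_start, col_stop)``.  ``axis`` is the unit direction of
    the tube's long axis in (row, col) coordinates; movement perpendicular
    to it is ignored.  ``food_position`` is the coordinate of the food end
    along that axis (pixels, same projection as centroids).
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    axis: tuple[float, float] = (0.0, 1.0)
    food_position: float = 0.0
    fly_id: str = "fly0"

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI rectangle must have positive extent")
        norm = float(np.hypot(*self.axis))
        if not np.isclose(norm, 1.0):
            object.__setattr__(self, "axis", (self.axis[0] / norm, self.axis[1] / norm))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        if (self.row_start < 0 or self.col_start < 0
                or self.row_stop > frame_shape[0] or self.col_stop > frame_shape[1]):
            raise ValueError(
                f"ROI {self!r} lies outside frame of shape {frame_shape}")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.row_start:self.row_stop, self.col_start:self.col_stop]

    def project(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Project absolute (row, col) coordinates onto the tube axis."""
        return rows * self.axis[0] + cols * self.axis[1]


@dataclass
class FlyObservation:
    """One fly's pixel set in one analyzed frame.

    ``pixels`` holds absolute (row, col) coordinates, one pixel per row.
    ``core_pixels`` / ``periphery_pixels`` partition ``pixels`` after the
    median grayscale split.  ``centroid_axis`` is the mean pixel position
    projected on the tube's long axis.
    """

    frame_index: int
    detected: bool
    pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    grays: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int16))
    centroid_axis: float = float("nan")
    core_pixels: np.ndarray | None = None
    periphery_pixels: np.ndarray | None = None

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])


def extract_foreground(frame: np.ndarray, background: np.ndarray,
                       c0: int = DEFAULT_C0) -> np.ndarray:
    """Binary mask of pixels darker than the background by more than ``c0``."""
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    return (background.astype(np.int16) - frame.astype(np.int16)) > c0


def extract_foreground_hysteresis(frame: np.ndarray, background: np.ndarray,
                                  c0: int = DEFAULT_C0,
                                  low_factor: float = 0.5) -> np.ndarray:
    """Foreground mask with hysteresis: seed at C0, extend to C0*low_factor.

    A connected region is foreground if it exceeds the weak threshold
    everywhere and the strict threshold somewhere.  Pixels whose
    contrast to the background hovers near C0 (e.g. a lightly pigmented
    fly on a bright background) then stop flickering in and out of the
    silhouette frame-to-frame, which would otherwise masquerade as
    periphery movement on a resting fly.  On noise-free input the
    result equals the strict mask.
    """
    diff = background.astype(np.int16) - frame.astype(np.int16)
    seed = diff > c0
    if not seed.any():
        return seed
    support = diff > c0 * low_factor
    labels = measure.label(support, connectivity=2)
    seeded = np.unique(labels[seed])
    seeded = seeded[seeded != 0]
    return np.isin(labels, seeded)


def remove_small_objects(mask: np.ndarray, c1: int = DEFAULT_C1) -> np.ndarray:
    """Erase connected components with area strictly less than ``c1``.

    8-connectivity; components of exactly ``c1`` pixels are retained.
    """
    return morphology.remove_small_objects(
        np.asarray(mask, dtype=bool), max_size=c1 - 1, connectivity=2)


def observe_fly(mask: np.ndarray, frame: np.ndarray, roi: TubeROI,
                frame_index: int = 0) -> FlyObservation:
    """Locate the fly (largest blob) inside ``roi`` and sample its grays.

    ``mask`` and ``frame`` are full-frame arrays; the returned pixel
    coordinates are absolute.  Ties in blob size go to the lowest label
    index (first-encountered component in raster order).
    """
    roi.validate_within(mask.shape)
    sub = roi.crop(np.asarray(mask, dtype=bool))
    labels = measure.label(sub, connectivity=2)
    n = labels.max()
    if n == 0:
        return FlyObservation(frame_index=frame_index, detected=False)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # argmax returns lowest index on ties
    rows, cols = np.nonzero(labels == best)
    rows = rows + roi.row_start
    cols = cols + roi.col_start
    pixels = np.column_stack([rows, cols]).astype(np.intp)
    grays = frame[rows, cols].astype(np.int16)
    centroid = float(np.mean(roi.project(rows.astype(float), cols.astype(float))))
    return FlyObservation(frame_index=frame_index, detected=True,
                          pixels=pixels, grays=grays, centroid_axis=centroid)


def split_core_periphery(obs: FlyObservation) -> FlyObservation:
    """Partition the fly body at its median grayscale into core/periphery.

    Pixels strictly darker than the median go to the core, strictly
    lighter to the periphery; pixels equal to the median are assigned to
    the core in pixel-index order until the core holds ceil(area/2)
    pixels, so the two halves differ in size by at most one.  A
    constant-gray blob degenerates to an index-order split into equal
    halves.
    """
    if not obs.detected or obs.area < 2:
        raise ValueError("core/periphery split requires a detected fly with >= 2 pixels")
    grays = obs.grays
    med = float(np.median(grays))
    target = -(-obs.area // 2)  # ceil(area / 2)
    core = grays < med
    n_core = int(core.sum())
    if n_core < target:
        eq_idx = np.nonzero(grays == med)[0]
        take = eq_idx[: target - n_core]
        core[take] = True
    obs.core_pixels = obs.pixels[core]
    obs.periphery_pixels = obs.pixels[~core]
    return obs
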