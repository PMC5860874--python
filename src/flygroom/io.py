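"""Plain-format I/O: PNG frame sequences, ROI configs, CSV tables.

Videos are exchanged as numbered 8-bit grayscale PNG frames in a
directory (``frame_000000.png``, ...); label streams, feature series,
training sets and binned series are CSV.  ROI configurations are JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import TrainingSet
from .segmentation import TubeROI

FRAME_PATTERN = "frame_{:06d}.png"


def write_png_sequence(video: np.ndarray, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(video):
        iio.imwrite(directory / FRAME_PATTERN.format(i), frame)
    return directory


def read_png_sequence(directory: str | Path) -> np.ndarray:
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    frames = [iio.imread(p) for p in paths]
    video = np.stack(frames)
    if video.ndim == 4:  # color input: average channels with a warning
        import warnings
        warnings.warn("color frames converted to grayscale by channel mean")
        video = video.mean(axis=-1).astype(np.uint8)
    return video


def write_rois(rois: list[TubeROI], path: str | Path) -> None:
    records = [{
        "fly_id": r.fly_id, "row_start": r.row_start, "row_stop": r.row_stop,
        "col_start": r.col_start, "col_stop": r.col_stop,
        "axis": list(r.axis), "food_position": r.food_position,
    } for r in rois]
    Path(path).write_text(json.dumps(records, indent=2))


def read_rois(path: str | Path) -> list[TubeROI]:
    records = json.loads(Path(path).read_text())
    return [TubeROI(row_start=r["row_start"], row_stop=r["row_stop"],
                    col_start=r["col_start"], col_stop=r["col_stop"],
                    axis=tuple(r.get("axis", (0.0, 1.0))),
                    food_position=float(r.get("food_position", 0.0)),
                    fly_id=r.get("fly_id", "fly0")) for r in records]


def write_labels(labels: np.ndarray, path: str | Path,
                 fly_id: str = "fly0", column: str = "behavior") -> None:
    pd.DataFrame({"fly_id": fly_id,
                  "analyzed_frame": np.arange(len(labels)),
                  column: labels}).to_csv(path, index=False)


def read_labels(path: str | Path, column: str = "behavior") -> np.ndarray:
    return pd.read_csv(path)[column].to_numpy(dtype=object)


def write_training_set(training: TrainingSet, path: str | Path) -> None:
    df = pd.DataFrame(training.samples, columns=["nPM", "nCM", "nCD"])
    df["label"] = training.labels
    df.to_csv(path, index=False)


def read_training_set(path: str | Path,
                      provenance: str | None = None) -> TrainingSet:
    df = pd.read_csv(path)
    required = {"nPM", "nCM", "nCD", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"training CSV must have columns {sorted(required)}")
    return TrainingSet(samples=df[["nPM", "nCM", "nCD"]].to_numpy(float),
                       labels=df["label"].to_numpy(object),
                       provenance=provenance or str(path))


def write_binned(binned, path: str | Path, fly_id: str = "fly0") -> None:
    df = binned.fractions.copy()
    df.insert(0, "bin_start_min",
              binned.t0_min + np.arange(len(df)) * binned.bin_minutes)
    if binned.lights is not None:
        df["lights_on"] = binned.lights
    df.insert(0, "fly_id", fly_id)
    df.to_csv(path, index=False)


def read_binned(path: str | Path):
    from .ethogram import BinnedSeries
    df = pd.read_csv(path)
    starts = df.pop("bin_start_min").to_numpy(float)
    lights = df.pop("lights_on").to_numpy(bool) if "lights_on" in df else None
    df = df.drop(columns=[c for c in ("fly_id",) if c in df])
    bin_minutes = float(starts[1] - starts[0]) if len(starts) > 1 else 30.0
    return BinnedSeries(bin_minutes=bin_minutes, fractions=df,
                        lights=lights, t0_min=float(starts[0]))
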