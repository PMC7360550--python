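"""Readers and writers for the pipeline's file formats.

Track tables are one-point-per-row CSVs with columns ``track_id, cell_id,
frame, x, y``; coordinates are converted to micrometres once at ingestion.
Masks are 2-D integer label images (TIFF or PNG), 0 = background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

logger = logging.getLogger("cometdyn")

TRACK_COLUMNS = ["track_id", "cell_id", "frame", "x", "y"]


class TrackTableFormatError(ValueError):
    """Malformed track file: missing columns or wrong dtypes."""


class TrackTableValidationError(ValueError):
    """Structurally valid file whose contents violate track invariants."""


@dataclass
class TrackTable:
    """Per-point comet track records in micrometres.

    ``data`` has columns ``track_id, cell_id, frame, x, y`` with x/y in um,
    sorted by (track_id, frame).  ``frame_interval`` is seconds per frame;
    ``pixel_size`` records the ingestion conversion factor (um/pixel).
    """

    data: pd.DataFrame
    pixel_size: float
    frame_interval: float
    unit: str = "um"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrackTableFormatError(f"missing track column(s): {missing}")
        self._validate()

    def _validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if (df["frame"] < 0).any():
            raise TrackTableValidationError("negative frame indices present")
        dup = df.duplicated(subset=["track_id", "frame"])
        if dup.any():
            tid = int(df.loc[dup, "track_id"].iloc[0])
            raise TrackTableValidationError(
                f"duplicated (track_id, frame) row in track {tid}"
            )
        for tid, grp in df.groupby("track_id", sort=False):
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise TrackTableValidationError(
                    f"frames not strictly increasing within track {int(tid)}"
                )
            if grp["cell_id"].nunique() > 1:
                raise TrackTableValidationError(
                    f"track {int(tid)} assigned to multiple cells"
                )

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def groupby_track(self):
        return self.data.groupby("track_id", sort=True)


@dataclass
class LabeledMask:
    """2-D integer label image: 0 = background, k > 0 = object k."""

    labels: np.ndarray
    pixel_size: float
    role: str = "tumor-cell"

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("mask contains non-integer pixel values")
            self.labels = as_int
        if self.labels.min() < 0:
            raise ValueError("mask labels must be non-negative")

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)


def read_track_table(
    path,
    pixel_size: float,
    frame_interval: float,
    coordinate_unit: str = "pixel",
) -> TrackTable:
    """Read a comet track CSV, converting coordinates to micrometres.

    Parameters
    ----------
    path:
        CSV with header ``track_id, cell_id, frame, x, y``.
    pixel_size:
        Micrometres per pixel of the source images.
    frame_interval:
        Seconds between consecutive frames.
    coordinate_unit:
        ``"pixel"`` if the file stores pixel coordinates (converted here),
        ``"um"`` if already metric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if coordinate_unit not in ("pixel", "um"):
        raise ValueError("coordinate_unit must be 'pixel' or 'um'")
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackTableFormatError(
            f"{path.name}: missing required column(s): {missing}"
        )
    df = df[TRACK_COLUMNS].copy()
    df["track_id"] = df["track_id"].astype(np.int64)
    df["cell_id"] = df["cell_id"].astype(np.int64)
    df["frame"] = df["frame"].astype(np.int64)
    if coordinate_unit == "pixel":
        df["x"] = df["x"].astype(float) * pixel_size
        df["y"] = df["y"].astype(float) * pixel_size
    df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    table = TrackTable(df, pixel_size=pixel_size, frame_interval=frame_interval)
    logger.info("read %d points / %d tracks from %s", len(df), table.n_tracks, path)
    return table


def write_track_table(table: TrackTable, path, coordinate_unit: str = "um") -> None:
    """Write a TrackTable to CSV (one point per row)."""
    df = table.data[TRACK_COLUMNS].copy()
    if coordinate_unit == "pixel":
        df["x"] = df["x"] / table.pixel_size
        df["y"] = df["y"] / table.pixel_size
    elif coordinate_unit != "um":
        raise ValueError("coordinate_unit must be 'pixel' or 'um'")
    df.to_csv(path, index=False)


def read_label_mask(path, pixel_size: float, role: str = "tumor-cell") -> LabeledMask:
    """Read a labeled mask image (TIFF or PNG) as integer labels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: mask must be a single 2-D image")
    mask = LabeledMask(arr, pixel_size=pixel_size, role=role)
    if mask.n_objects == 0:
        warnings.warn(f"{path.name}: mask contains no labeled objects", stacklevel=2)
    logger.info("read mask %s: %d object(s)", path, mask.n_objects)
    return mask


def write_label_mask(mask: LabeledMask, path) -> None:
    """Write a labeled mask as TIFF (or PNG for small label counts)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.labels.astype(np.int32))
    else:
        labels = mask.labels
        if labels.max() > 65535:
            raise ValueError("PNG masks support at most 16-bit labels")
        Image.fromarray(labels.astype(np.uint16)).save(path)


def read_movie(path) -> np.ndarray:
    """Read a time-lapse TIFF stack as a (frames, y, x) array."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("movie must be a 2-D frame or a 3-D stack")
    return arr


def write_movie(stack: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(stack))
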