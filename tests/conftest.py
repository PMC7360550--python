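"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cometdyn.features import Track
from cometdyn.geometry import geometries_for_mask
from cometdyn.io import TrackTable
from cometdyn.synthetic import ShapeSimSpec, TrackSimSpec, simulate_cell_mask, simulate_tracks


def make_track(points, track_id=1, cell_id=1, frame_interval=1.0, frames=None):
    """Build a Track from a list of (x, y) micrometre points."""
    pts = np.asarray(points, float)
    if frames is None:
        frames = np.arange(len(pts))
    return Track(
        track_id=track_id,
        cell_id=cell_id,
        frames=np.asarray(frames),
        x=pts[:, 0],
        y=pts[:, 1],
        frame_interval=frame_interval,
    )


def make_direction_track(angle, track_id, start=(10.0, 10.0), step=0.5, n=5,
                         cell_id=1):
    """Straight track of unit direction `angle` starting at `start`."""
    u = np.array([np.cos(angle), np.sin(angle)])
    pts = np.asarray(start, float) + np.outer(np.arange(n) * step, u)
    return make_track(pts, track_id=track_id, cell_id=cell_id)


def table_from_tracks(tracks, pixel_size=0.25, frame_interval=1.0):
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, t.cell_id, int(f), x, y))
    df = pd.DataFrame(rows, columns=["track_id", "cell_id", "frame", "x", "y"])
    return TrackTable(df, pixel_size=pixel_size, frame_interval=frame_interval)


@pytest.fixture(scope="session")
def small_mask():
    mask, gt = simulate_cell_mask(ShapeSimSpec(n_cells=3, seed=1))
    return mask, gt


@pytest.fixture(scope="session")
def small_dataset(small_mask):
    mask, mask_gt = small_mask
    table, track_gt = simulate_tracks(
        TrackSimSpec(n_cells=3, tracks_per_cell=25, kappa_dir=2.0, seed=1), mask
    )
    geoms = geometries_for_mask(mask)
    return mask, table, geoms, track_gt
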