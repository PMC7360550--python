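"""Simplified comet detection and frame-to-frame linking.

A difference-of-Gaussians band-pass isolates comet-scale structure; local
maxima above a robust noise threshold are refined to sub-pixel positions by
an intensity-weighted centroid; detections are linked across frames by
mutual-nearest-neighbor matching with a distance gate, bridging at most one
missing frame.  This stage is intentionally conservative (fragmentation
over identity switches) — it is a front end for synthetic benchmark movies,
not a re-implementation of multi-hypothesis trackers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from cometdyn.io import LabeledMask, TrackTable


@dataclass
class DetectionParams:
    """Band-pass sigmas in pixels, threshold in robust-SD units above
    background, link gate in um per frame."""

    lowpass_sigma: float = 1.5
    highpass_sigma: float = 4.5
    threshold_sd: float = 2.5
    max_link_distance_um: float = 1.5
    max_gap_frames: int = 1
    pixel_size: float = 0.25
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.lowpass_sigma >= self.highpass_sigma:
            raise ValueError("lowpass_sigma must be < highpass_sigma")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.max_gap_frames not in (0, 1):
            raise ValueError("max_gap_frames must be 0 or 1")


def bandpass_filter(frame: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Difference-of-Gaussians band-pass; constant images map to zero."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("bandpass_filter expects a single 2-D frame")
    low = ndimage.gaussian_filter(frame, params.lowpass_sigma)
    high = ndimage.gaussian_filter(frame, params.highpass_sigma)
    return low - high


def robust_background_sd(bandpassed: np.ndarray) -> float:
    """Noise SD from the median absolute deviation (robust to bright spots)."""
    med = np.median(bandpassed)
    mad = np.median(np.abs(bandpassed - med))
    return float(1.4826 * mad)


def detect_comets(frame: np.ndarray, params: DetectionParams) -> pd.DataFrame:
    """Detect comet candidates in one raw frame.

    Returns a DataFrame (x_px, y_px, intensity): local maxima of the
    band-passed frame above ``threshold_sd`` robust SDs over the background
    median, refined by a 3x3 intensity-weighted centroid.
    """
    bp = bandpass_filter(frame, params)
    sd = robust_background_sd(bp)
    thresh = np.median(bp) + params.threshold_sd * sd
    if sd == 0:
        thresh = np.median(bp) + 1e-9
    footprint = np.ones((3, 3), bool)
    is_max = (bp == ndimage.maximum_filter(bp, footprint=footprint)) & (bp > thresh)
    rows, cols = np.nonzero(is_max)
    out = []
    h, w = bp.shape
    for r, c in zip(rows, cols):
        r0, r1 = max(r - 1, 0), min(r + 2, h)
        c0, c1 = max(c - 1, 0), min(c + 2, w)
        win = bp[r0:r1, c0:c1]
        win = np.clip(win, 0, None)
        total = win.sum()
        if total <= 0:
            cy, cx = float(r), float(c)
        else:
            ri, ci = np.mgrid[r0:r1, c0:c1]
            cy = float((ri * win).sum() / total)
            cx = float((ci * win).sum() / total)
        out.append((cx, cy, float(bp[r, c])))
    return pd.DataFrame(out, columns=["x_px", "y_px", "intensity"])


def detect_movie(stack: np.ndarray, params: DetectionParams) -> list[pd.DataFrame]:
    return [detect_comets(frame, params) for frame in stack]


def _mutual_nn(
    sources: np.ndarray, targets: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Mutual nearest-neighbor pairs within the gate distance."""
    if len(sources) == 0 or len(targets) == 0:
        return []
    d = np.linalg.norm(sources[:, None, :] - targets[None, :, :], axis=2)
    nn_t = d.argmin(axis=1)
    nn_s = d.argmin(axis=0)
    pairs = []
    for i, j in enumerate(nn_t):
        if nn_s[j] == i and d[i, j] <= gate:
            pairs.append((i, int(j)))
    return pairs


def link_comets(
    detections: list[pd.DataFrame],
    params: DetectionParams,
    mask: LabeledMask | None = None,
) -> TrackTable:
    """Link per-frame detections into comet tracks.

    Matching is mutual-nearest-neighbor with gate ``max_link_distance_um``;
    a track that misses one frame may be recovered in the next frame with a
    doubled gate (one gap maximum).  Cell ids are read from the tumor mask
    at each track's first point (0 with a warning when no mask is given).
    Tracks with fewer than two points are discarded.
    """
    if len(detections) < 2:
        raise ValueError("need detections from at least 2 frames to link")
    ps = params.pixel_size
    gate = params.max_link_distance_um

    # active track state: id -> (last position um, last frame, gap used)
    tracks: dict[int, list[tuple[int, float, float]]] = {}
    active: dict[int, tuple[np.ndarray, int]] = {}
    next_id = 1

    for f, det in enumerate(detections):
        pts = det[["x_px", "y_px"]].to_numpy(float) * ps if len(det) else \
            np.empty((0, 2))
        unmatched = set(range(len(pts)))

        # pass 1: tracks seen in the previous frame
        fresh = {tid: st for tid, st in active.items() if st[1] == f - 1}
        tids = list(fresh)
        pairs = _mutual_nn(
            np.array([fresh[t][0] for t in tids]).reshape(-1, 2),
            pts, gate,
        )
        matched_tracks = set()
        for i, j in pairs:
            tid = tids[i]
            tracks[tid].append((f, pts[j, 0], pts[j, 1]))
            active[tid] = (pts[j], f)
            matched_tracks.add(tid)
            unmatched.discard(j)

        # pass 2: gap closing for tracks last seen two frames ago
        if params.max_gap_frames >= 1:
            stale = {
                tid: st for tid, st in active.items()
                if st[1] == f - 2 and tid not in matched_tracks
            }
            tids2 = list(stale)
            rest = sorted(unmatched)
            pairs2 = _mutual_nn(
                np.array([stale[t][0] for t in tids2]).reshape(-1, 2),
                pts[rest].reshape(-1, 2) if rest else np.empty((0, 2)),
                2 * gate,
            )
            for i, j in pairs2:
                tid = tids2[i]
                k = rest[j]
                tracks[tid].append((f, pts[k, 0], pts[k, 1]))
                active[tid] = (pts[k], f)
                unmatched.discard(k)

        for j in sorted(unmatched):
            tracks[next_id] = [(f, pts[j, 0], pts[j, 1])]
            active[next_id] = (pts[j], f)
            next_id += 1

        # expire tracks that can no longer be extended
        horizon = f - 1 - params.max_gap_frames
        active = {tid: st for tid, st in active.items() if st[1] > horizon}

    if mask is None:
        warnings.warn("no cell mask given; tracks emitted with cell_id 0",
                      stacklevel=2)

    rows = []
    out_id = 0
    for tid in sorted(tracks):
        pts = tracks[tid]
        if len(pts) < 2:
            continue
        out_id += 1
        if mask is not None:
            col = int(round(pts[0][1] / ps))
            row = int(round(pts[0][2] / ps))
            h, w = mask.labels.shape
            cell = int(mask.labels[min(row, h - 1), min(col, w - 1)])
        else:
            cell = 0
        for f, x, y in pts:
            rows.append((out_id, cell, f, x, y))

    df = pd.DataFrame(rows, columns=["track_id", "cell_id", "frame", "x", "y"])
    return TrackTable(df, pixel_size=ps, frame_interval=params.frame_interval)


def track_movie(
    stack: np.ndarray,
    params: DetectionParams,
    mask: LabeledMask | None = None,
) -> TrackTable:
    """Detect and link a whole movie in one call."""
    return link_comets(detect_movie(stack, params), params, mask=mask)
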