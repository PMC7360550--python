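"""Strict track filters and the 14 per-track comet dynamics features.

For every surviving track the pipeline computes four speed statistics,
net displacement, path length, persistence, mean curvature, three
cell-normalized location features (distance to edge / major axis / minor
axis), local and cellular directional coherence, and orientation to the
cell's major axis.  Directions are unit net-displacement vectors; coherence
is the average cosine between a track's direction and the directions of the
tracks in its scope (20-um neighborhood for local, the whole cell for
cellular), including the query itself by default so that parallel tracks
score 1.0 and a symmetric radial arrangement scores exactly 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cometdyn.config import RunConfig
from cometdyn.geometry import CellGeometry
from cometdyn.io import TrackTable

#: canonical order of the 14 feature columns
FEATURE_COLUMNS = [
    "speed_avg",
    "speed_min",
    "speed_max",
    "speed_sd",
    "displacement",
    "path_length",
    "persistence",
    "curvature",
    "dist_edge_norm",
    "dist_major_norm",
    "dist_minor_norm",
    "local_coherence",
    "cellular_coherence",
    "orientation",
]

FILTER_RULES = [
    "in_marked_cell",
    "cell_fov_fraction",
    "min_frames",
    "max_gaps",
    "min_displacement",
    "min_persistence",
]


@dataclass
class Track:
    """One comet trajectory: time-ordered (frame, x, y) in micrometres."""

    track_id: int
    cell_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames must increase")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds; gaps keep their true spacing."""
        return self.frames * self.frame_interval

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def n_missing_frames(self) -> int:
        return int((np.diff(self.frames) - 1).sum())

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.x.mean(), self.y.mean()])

    @property
    def displacement_vector(self) -> np.ndarray:
        return np.array([self.x[-1] - self.x[0], self.y[-1] - self.y[0]])

    def direction(self) -> np.ndarray:
        """Unit net-displacement vector."""
        v = self.displacement_vector
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"track {self.track_id}: zero net displacement")
        return v / norm


def tracks_from_table(table: TrackTable) -> list[Track]:
    out = []
    for tid, grp in table.groupby_track():
        if len(grp) < 2:
            continue
        out.append(
            Track(
                track_id=int(tid),
                cell_id=int(grp["cell_id"].iloc[0]),
                frames=grp["frame"].to_numpy(),
                x=grp["x"].to_numpy(float),
                y=grp["y"].to_numpy(float),
                frame_interval=table.frame_interval,
            )
        )
    return out


# ---------------------------------------------------------------- kinematics

def speed_stats(track: Track) -> tuple[float, float, float, float]:
    """(average, min, max, SD) of per-frame speeds.

    Per-frame velocity uses central differences on the true acquisition
    times (one-sided at the endpoints), so a bridged one-frame gap
    contributes a physically sensible speed over the doubled interval.
    """
    t = track.times
    vx = np.gradient(track.x, t)
    vy = np.gradient(track.y, t)
    speeds = np.hypot(vx, vy)
    return (
        float(speeds.mean()),
        float(speeds.min()),
        float(speeds.max()),
        float(speeds.std()),
    )


def path_geometry(track: Track) -> tuple[float, float, float]:
    """(net displacement, path length, persistence = displacement/path)."""
    disp = float(np.linalg.norm(track.displacement_vector))
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    path = float(steps.sum())
    persistence = disp / path if path > 0 else 0.0
    return disp, path, persistence


def mean_curvature(track: Track, variant: str = "standard") -> float:
    """Mean curvature (1/um) of a cubic-polynomial fit to the track.

    x(t) and y(t) are fit by least squares with degree min(3, n-1) and
    differentiated analytically; curvature is evaluated at each acquisition
    time and averaged.

    ``variant="standard"`` uses the plane-curve formula
    |x'y'' - y'x''| / (x'^2 + y'^2)^{3/2}.  ``variant="as_printed"``
    evaluates |x'(y')^2 - y'(x')^2| / (x'^2 + y'^2)^{3/2}, a legacy form
    kept for comparison with earlier analyses; it is not a geometric
    curvature (it does not vanish on oblique straight lines).

    Returns NaN for stationary tracks (zero derivatives everywhere).
    """
    if variant not in ("standard", "as_printed"):
        raise ValueError("variant must be 'standard' or 'as_printed'")
    t = track.times
    deg = min(3, track.n_points - 1)
    # center time for conditioning; derivatives are shift-invariant
    tc = t - t.mean()
    px = np.polynomial.Polynomial.fit(tc, track.x, deg).convert()
    py = np.polynomial.Polynomial.fit(tc, track.y, deg).convert()
    dx, dy = px.deriv()(tc), py.deriv()(tc)
    speed_sq = dx**2 + dy**2
    ok = speed_sq > 1e-18
    if not ok.any():
        return float("nan")
    if variant == "standard":
        ddx, ddy = px.deriv(2)(tc), py.deriv(2)(tc)
        num = np.abs(dx * ddy - dy * ddx)
    else:
        num = np.abs(dx * dy**2 - dy * dx**2)
    kappa = num[ok] / speed_sq[ok] ** 1.5
    return float(kappa.mean())


# ---------------------------------------------------------------- location

def raw_edge_distance(track: Track, geom: CellGeometry) -> float:
    """Mean distance-transform value along the track, divided by the cell's
    mean interior distance (cell-size normalization; min-max scaling to
    [0, 1] across each cell's tracks happens at table assembly)."""
    vals = [geom.distance_to_edge(xi, yi) for xi, yi in zip(track.x, track.y)]
    return float(np.mean(vals)) / geom.mean_interior_distance


def axis_distances(track: Track, geom: CellGeometry) -> tuple[float, float]:
    """Normalized perpendicular distance of the track centroid to the cell
    major and minor axis lines, each divided by the farthest boundary point
    from that axis and clamped to [0, 1]."""
    c = track.centroid
    out = []
    for axis in ("major", "minor"):
        d = geom.axis_line_distance(c, axis)
        dmax = geom.max_boundary_axis_distance(axis)
        out.append(min(d / dmax, 1.0) if dmax > 0 else 0.0)
    return out[0], out[1]


def orientation_to_major_axis(track: Track, geom: CellGeometry) -> float:
    """cos of the acute angle between the track's net displacement and the
    cell major axis: 1 = parallel, 0 = perpendicular."""
    u = track.direction()
    axis = np.array([np.cos(geom.major_axis_angle), np.sin(geom.major_axis_angle)])
    return float(abs(np.dot(u, axis)))


# ---------------------------------------------------------------- coherence

def track_coherence(
    query: Track,
    cohort: list[Track],
    radius_um: float | None = None,
    include_self: bool = True,
) -> float:
    """Average direction cosine between a query track and its scope.

    The scope is the cohort tracks (same cell) whose centroids lie within
    ``radius_um`` of the query centroid, or all cohort tracks when
    ``radius_um`` is None (cellular coherence).  With ``include_self``
    (default) the query's own direction is part of the average.
    """
    uq = query.direction()
    qc = query.centroid
    cosines = []
    for other in cohort:
        if other.track_id == query.track_id and not include_self:
            continue
        if radius_um is not None:
            if np.linalg.norm(other.centroid - qc) > radius_um:
                continue
        cosines.append(float(np.dot(uq, other.direction())))
    if not cosines:
        return float("nan")
    return float(np.mean(cosines))


def cellular_coherence_of_cell(
    cohort: list[Track], include_self: bool = True
) -> float:
    """Cell-level cellular coherence: per-track cellular coherence averaged
    over the cell's tracks.  With self-inclusive averaging this equals the
    squared length of the mean unit-direction vector."""
    vals = [
        track_coherence(t, cohort, radius_um=None, include_self=include_self)
        for t in cohort
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------- filtering

def filter_tracks(
    table: TrackTable,
    geometries: dict[int, CellGeometry],
    config: RunConfig | None = None,
) -> tuple[TrackTable, pd.DataFrame]:
    """Apply the strict track filters; return survivors and a rejection report.

    Rules, in order (the first failing rule is charged):

    1. the track lies in a marked cell (cell_id present in the mask);
    2. the cell keeps >= ``min_fraction_in_fov`` of its body in view;
    3. detected in >= ``min_frames`` frames;
    4. at most ``max_gaps`` missing frame(s);
    5. travels >= ``min_displacement_um`` (net displacement by default);
    6. persistence > ``min_persistence``.
    """
    config = config or RunConfig()
    counts = dict.fromkeys(FILTER_RULES, 0)
    keep_ids: list[int] = []

    for track in tracks_from_table(table):
        geom = geometries.get(track.cell_id)
        if track.cell_id <= 0 or geom is None:
            counts["in_marked_cell"] += 1
            continue
        if geom.fraction_in_fov < config.min_fraction_in_fov:
            counts["cell_fov_fraction"] += 1
            continue
        if track.n_points < config.min_frames:
            counts["min_frames"] += 1
            continue
        if track.n_missing_frames > config.max_gaps:
            counts["max_gaps"] += 1
            continue
        disp, path, persistence = path_geometry(track)
        travel = disp if config.displacement_rule == "net" else path
        if travel < config.min_displacement_um:
            counts["min_displacement"] += 1
            continue
        if persistence <= config.min_persistence:
            counts["min_persistence"] += 1
            continue
        keep_ids.append(track.track_id)

    kept = table.data[table.data["track_id"].isin(keep_ids)].reset_index(drop=True)
    report = pd.DataFrame(
        {"rule": list(counts), "n_rejected": list(counts.values())}
    )
    filtered = TrackTable(
        kept, pixel_size=table.pixel_size, frame_interval=table.frame_interval
    )
    return filtered, report


# ---------------------------------------------------------------- assembly

def compute_feature_table(
    table: TrackTable,
    geometries: dict[int, CellGeometry],
    config: RunConfig | None = None,
    condition: str = "",
    batch: str = "",
) -> pd.DataFrame:
    """One row per track with all 14 features plus cell/condition/batch labels.

    ``table`` should already have passed :func:`filter_tracks`.  Rows with
    any undefined feature (stationary track, empty coherence scope) are
    dropped; the number dropped is recorded in ``df.attrs["n_dropped"]``.
    The edge-distance feature is min-max scaled within each cell (or over
    the whole dataset with ``config.edge_norm_scope = "dataset"``); if all
    of a scope's raw values coincide the feature is set to 1.0.
    """
    config = config or RunConfig()
    tracks = tracks_from_table(table)
    by_cell: dict[int, list[Track]] = {}
    for tr in tracks:
        by_cell.setdefault(tr.cell_id, []).append(tr)

    rows = []
    for cell_id, cohort in sorted(by_cell.items()):
        geom = geometries.get(cell_id)
        if geom is None:
            continue
        for tr in cohort:
            disp, path, persistence = path_geometry(tr)
            if disp == 0:
                continue
            avg, mn, mx, sd = speed_stats(tr)
            x2, x3 = axis_distances(tr, geom)
            rows.append(
                {
                    "track_id": tr.track_id,
                    "cell_id": cell_id,
                    "condition": condition,
                    "batch": batch,
                    "speed_avg": avg,
                    "speed_min": mn,
                    "speed_max": mx,
                    "speed_sd": sd,
                    "displacement": disp,
                    "path_length": path,
                    "persistence": persistence,
                    "curvature": mean_curvature(tr, config.curvature_variant),
                    "_raw_edge": raw_edge_distance(tr, geom),
                    "dist_major_norm": x2,
                    "dist_minor_norm": x3,
                    "local_coherence": track_coherence(
                        tr,
                        cohort,
                        radius_um=config.coherence_radius_um,
                        include_self=config.coherence_include_self,
                    ),
                    "cellular_coherence": track_coherence(
                        tr,
                        cohort,
                        radius_um=None,
                        include_self=config.coherence_include_self,
                    ),
                    "orientation": orientation_to_major_axis(tr, geom),
                }
            )

    if not rows:
        df = pd.DataFrame(
            columns=["track_id", "cell_id", "condition", "batch"] + FEATURE_COLUMNS
        )
        df.attrs["n_dropped"] = 0
        return df

    df = pd.DataFrame(rows)

    def _minmax(s: pd.Series) -> pd.Series:
        span = s.max() - s.min()
        if span == 0:
            return pd.Series(1.0, index=s.index)
        return (s - s.min()) / span

    if config.edge_norm_scope == "cell":
        df["dist_edge_norm"] = df.groupby("cell_id")["_raw_edge"].transform(_minmax)
    else:
        df["dist_edge_norm"] = _minmax(df["_raw_edge"])
    df = df.drop(columns="_raw_edge")

    n_before = len(df)
    df = df.dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)
    df = df[["track_id", "cell_id", "condition", "batch"] + FEATURE_COLUMNS]
    df.attrs["n_dropped"] = n_before - len(df)
    return df
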