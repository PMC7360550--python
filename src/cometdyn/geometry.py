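"""Per-cell geometry extracted from labeled masks.

A :class:`CellGeometry` bundles everything the track features need about
one cell: the centroid and second-moment ellipse axes (in the image x/y
convention, x = column, y = row, angles measured from the +x axis), the
boundary contour, and the interior distance transform in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from cometdyn.io import LabeledMask


class DegenerateGeometryError(ValueError):
    """Cell too small or thin for moment-based geometry."""


@dataclass
class CellGeometry:
    cell_id: int
    centroid: np.ndarray          # (x, y) in um
    major_axis_angle: float       # radians from +x axis, in (-pi/2, pi/2]
    major_axis_length: float      # um
    minor_axis_length: float      # um
    boundary: np.ndarray          # (n, 2) contour points (x, y) in um
    distance_um: np.ndarray       # full-frame distance transform (um), 0 outside
    mean_interior_distance: float # um, over interior pixels
    area_um2: float
    fraction_in_fov: float
    pixel_size: float
    _mask: np.ndarray = None      # boolean mask of this cell

    @property
    def minor_axis_angle(self) -> float:
        a = self.major_axis_angle + np.pi / 2
        return a - np.pi if a > np.pi / 2 else a

    def contains(self, x_um: float, y_um: float) -> bool:
        col = int(round(x_um / self.pixel_size))
        row = int(round(y_um / self.pixel_size))
        if not (0 <= row < self._mask.shape[0] and 0 <= col < self._mask.shape[1]):
            return False
        return bool(self._mask[row, col])

    def distance_to_edge(self, x_um: float, y_um: float) -> float:
        """Distance-transform value at a point; falls back to the nearest
        interior pixel for points marginally outside the mask."""
        col = int(round(x_um / self.pixel_size))
        row = int(round(y_um / self.pixel_size))
        row = np.clip(row, 0, self._mask.shape[0] - 1)
        col = np.clip(col, 0, self._mask.shape[1] - 1)
        if self._mask[row, col]:
            return float(self.distance_um[row, col])
        rows, cols = np.nonzero(self._mask)
        i = np.argmin((rows - row) ** 2 + (cols - col) ** 2)
        return float(self.distance_um[rows[i], cols[i]])

    def axis_line_distance(self, point_um: np.ndarray, axis: str) -> float:
        """Perpendicular distance (um) from a point to the major/minor axis
        line through the centroid."""
        angle = self.major_axis_angle if axis == "major" else self.minor_axis_angle
        normal = np.array([-np.sin(angle), np.cos(angle)])
        return abs(float(np.dot(np.asarray(point_um) - self.centroid, normal)))

    def max_boundary_axis_distance(self, axis: str) -> float:
        """Farthest boundary point from the major/minor axis line (um)."""
        angle = self.major_axis_angle if axis == "major" else self.minor_axis_angle
        normal = np.array([-np.sin(angle), np.cos(angle)])
        return float(np.abs((self.boundary - self.centroid) @ normal).max())


def _principal_axis_angle(mask_bool: np.ndarray) -> float:
    """Major-axis angle from the +x (column) axis via second central moments."""
    rows, cols = np.nonzero(mask_bool)
    x = cols - cols.mean()
    y = rows - rows.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, np.argmax(evals)]
    angle = np.arctan2(vy, vx)
    # fold to (-pi/2, pi/2]: an axis has no direction
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return float(angle)


def cell_geometry_from_mask(
    mask: LabeledMask,
    cell_id: int,
    fov_bounds: tuple | None = None,
) -> CellGeometry:
    """Extract the geometry of one labeled cell.

    ``fov_bounds`` is an optional (row_min, row_max, col_min, col_max) pixel
    box; ``fraction_in_fov`` is the fraction of the cell's area inside it
    (cells clipped by the image border report area-inside / area-total,
    which is conservative for the >=80 %-in-view filter).
    """
    cell = mask.labels == cell_id
    n_pix = int(cell.sum())
    if n_pix == 0:
        raise ValueError(f"cell_id {cell_id} not present in mask")
    if n_pix < 4:
        raise DegenerateGeometryError(
            f"cell {cell_id} has only {n_pix} pixel(s); geometry undefined"
        )

    props = measure.regionprops(cell.astype(np.uint8))[0]
    ps = mask.pixel_size
    cy, cx = props.centroid
    major = props.axis_major_length * ps
    minor = props.axis_minor_length * ps
    if minor <= 0:
        raise DegenerateGeometryError(f"cell {cell_id} is degenerate (zero width)")

    angle = _principal_axis_angle(cell)

    dt = ndimage.distance_transform_edt(cell) * ps
    mean_dist = float(dt[cell].mean())

    contours = measure.find_contours(cell.astype(float), 0.5)
    boundary_rc = max(contours, key=len)
    boundary = np.column_stack([boundary_rc[:, 1], boundary_rc[:, 0]]) * ps

    if fov_bounds is not None:
        r0, r1, c0, c1 = fov_bounds
        inside = cell[max(r0, 0):r1, max(c0, 0):c1].sum()
        frac = inside / n_pix
    else:
        frac = 1.0

    return CellGeometry(
        cell_id=int(cell_id),
        centroid=np.array([cx, cy]) * ps,
        major_axis_angle=angle,
        major_axis_length=major,
        minor_axis_length=minor,
        boundary=boundary,
        distance_um=dt,
        mean_interior_distance=mean_dist,
        area_um2=n_pix * ps**2,
        fraction_in_fov=float(frac),
        pixel_size=ps,
        _mask=cell,
    )


def geometries_for_mask(mask: LabeledMask, fov_bounds=None) -> dict[int, CellGeometry]:
    """CellGeometry for every labeled object, skipping degenerate ones."""
    out: dict[int, CellGeometry] = {}
    for cid in mask.object_ids:
        try:
            out[int(cid)] = cell_geometry_from_mask(mask, int(cid), fov_bounds)
        except DegenerateGeometryError:
            continue
    return out
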