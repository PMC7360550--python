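"""Elliptical cell-mask generator with analytic ground truth.

Cells are ellipses (optionally roughened by low-order radial Fourier
perturbations) placed without overlap in a square field and rasterized at a
configurable pixel size.  Ground truth (area, perimeter, circularity,
major-axis angle) is computed from the generating boundary curve before
rasterization; for smooth ellipses the perimeter is the exact
elliptic-integral value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from skimage import draw

from cometdyn.io import LabeledMask


class PlacementError(RuntimeError):
    """Could not place all cells without overlap; use a larger field."""


@dataclass
class ShapeSimSpec:
    """Parameters of the cell-mask generator.

    ``axis_ratio_range`` is the major/minor ratio (>= 1), ``area_range`` in
    um^2 (defaults around a 300 um^2 tumor cell), ``boundary_roughness`` in
    [0, 1] scales radial Fourier perturbations of the ellipse boundary.
    """

    n_cells: int = 5
    axis_ratio_range: tuple = (1.5, 3.0)
    area_range: tuple = (200.0, 400.0)
    boundary_roughness: float = 0.0
    pixel_size: float = 0.25
    field_size_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.axis_ratio_range[0] < 1:
            raise ValueError("axis_ratio must be >= 1")
        if self.area_range[0] <= 0:
            raise ValueError("area must be positive")
        if not 0 <= self.boundary_roughness <= 1:
            raise ValueError("boundary_roughness must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter 4 a E(e^2) via the complete elliptic integral."""
    a, b = max(a, b), min(a, b)
    e_sq = 1.0 - (b / a) ** 2
    return float(4 * a * special.ellipe(e_sq))


def _boundary_polygon(
    a: float, b: float, angle: float, roughness: float, rng: np.random.Generator,
    n_vertices: int = 720,
) -> np.ndarray:
    """Dense boundary polygon of a (possibly roughened) ellipse, centered at 0."""
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r_mod = np.ones_like(phi)
    if roughness > 0:
        # low-order radial modes; amplitude capped so the boundary stays simple
        for order in (3, 4, 5):
            amp = roughness * 0.08 * rng.uniform(0.5, 1.0)
            r_mod += amp * np.cos(order * phi + rng.uniform(0, 2 * np.pi))
    ex = a * np.cos(phi) * r_mod
    ey = b * np.sin(phi) * r_mod
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack([ca * ex - sa * ey, sa * ex + ca * ey])


def _polygon_area_perimeter(poly: np.ndarray) -> tuple[float, float]:
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    closed = np.vstack([poly, poly[:1]])
    perim = np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1])).sum()
    return float(area), float(perim)


def simulate_cell_mask(
    spec: ShapeSimSpec,
    max_tries: int = 200,
) -> tuple[LabeledMask, pd.DataFrame]:
    """Generate a labeled mask of non-overlapping cells plus ground truth.

    Returns the mask and a table with one row per cell: label, center,
    semi-axes, major-axis angle (radians, from +x), true area, perimeter
    and circularity of the generating boundary.
    """
    rng = np.random.default_rng(spec.seed)
    ratios = rng.uniform(*spec.axis_ratio_range, spec.n_cells)
    areas = rng.uniform(*spec.area_range, spec.n_cells)
    semi_a = np.sqrt(areas * ratios / np.pi)
    semi_b = np.sqrt(areas / (ratios * np.pi))

    margin = semi_a.max() * (1 + spec.boundary_roughness * 0.3) + 2 * spec.pixel_size
    if spec.field_size_um is None:
        # pack with generous spacing: ~9x the summed bounding-disk area
        field = max(3.0 * np.sqrt(np.sum((2 * margin) ** 2 * spec.n_cells / 4)),
                    4 * margin)
    else:
        field = spec.field_size_um

    centers = np.empty((spec.n_cells, 2))
    radii = semi_a * (1 + spec.boundary_roughness * 0.3)
    for i in range(spec.n_cells):
        for _ in range(max_tries):
            c = rng.uniform(margin, field - margin, 2)
            if i == 0 or np.all(
                np.linalg.norm(centers[:i] - c, axis=1) > radii[:i] + radii[i] + 1.0
            ):
                centers[i] = c
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{spec.n_cells}; "
                "increase field_size_um or reduce n_cells/area"
            )

    n_px = int(np.ceil(field / spec.pixel_size))
    labels = np.zeros((n_px, n_px), dtype=np.int32)
    records = []
    for i in range(spec.n_cells):
        angle = rng.uniform(-np.pi / 2, np.pi / 2)
        poly = _boundary_polygon(
            semi_a[i], semi_b[i], angle, spec.boundary_roughness, rng
        )
        true_area, true_perim = _polygon_area_perimeter(poly)
        if spec.boundary_roughness == 0:
            true_perim = ellipse_perimeter(semi_a[i], semi_b[i])
            true_area = np.pi * semi_a[i] * semi_b[i]
        world = poly + centers[i]
        rr, cc = draw.polygon(
            world[:, 1] / spec.pixel_size, world[:, 0] / spec.pixel_size,
            shape=labels.shape,
        )
        labels[rr, cc] = i + 1
        records.append(
            {
                "cell_id": i + 1,
                "center_x_um": centers[i, 0],
                "center_y_um": centers[i, 1],
                "semi_major_um": semi_a[i],
                "semi_minor_um": semi_b[i],
                "major_axis_angle": angle,
                "true_area_um2": true_area,
                "true_perimeter_um": true_perim,
                "true_circularity": 4 * np.pi * true_area / true_perim**2,
            }
        )

    mask = LabeledMask(labels, pixel_size=spec.pixel_size, role="tumor-cell")
    return mask, pd.DataFrame(records)
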