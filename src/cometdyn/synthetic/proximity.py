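"""Tumor-cell / macrophage proximity fields with a tunable association.

Macrophages are placed first.  A fixed fraction of tumor cells is seeded
in contact with a macrophage (touching its disk) regardless of shape, the
rest uniformly, so contact and far categories are both populated.  Each
cell's probability of being elongated (low circularity) is then shifted on
the log-odds scale by ``association_strength`` when it is a contact cell;
at strength 0 shape and proximity are independent, so enrichment tests on
these fields measure their type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw

from cometdyn.io import LabeledMask
from cometdyn.synthetic.masks import (
    PlacementError,
    _boundary_polygon,
    ellipse_perimeter,
)


@dataclass
class ProximitySimSpec:
    n_tumor_cells: int = 30
    n_macrophages: int = 12
    field_size_um: float = 450.0
    association_strength: float = 0.0
    contact_distance_um: float = 5.0
    macrophage_radius_um: float = 5.0
    cell_area_um2: float = 300.0
    base_elongation_prob: float = 0.2
    near_fraction: float = 0.4
    elongated_axis_ratio: tuple = (5.0, 8.0)
    round_axis_ratio: tuple = (1.0, 1.3)
    pixel_size: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor_cells < 1:
            raise ValueError("n_tumor_cells must be >= 1")
        if self.n_macrophages < 0:
            raise ValueError("n_macrophages must be >= 0")
        if self.field_size_um <= 0 or self.pixel_size <= 0:
            raise ValueError("field and pixel size must be positive")
        if not 0 <= self.near_fraction <= 1:
            raise ValueError("near_fraction must be in [0, 1]")


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_proximity_field(
    spec: ProximitySimSpec, max_tries: int = 300
) -> tuple[LabeledMask, LabeledMask, pd.DataFrame]:
    """Generate tumor and macrophage masks plus a ground-truth table.

    Ground truth records, per tumor cell: its true boundary-to-macrophage
    distance, whether it came from the elongated mixture component, and its
    analytic circularity.  With no macrophages every distance is the field
    diagonal and flagged ``no_macrophage``.
    """
    rng = np.random.default_rng(spec.seed)
    field = spec.field_size_um
    n_px = int(np.ceil(field / spec.pixel_size))
    r_mac = spec.macrophage_radius_um
    no_mac = spec.n_macrophages == 0
    diag = float(np.hypot(field, field))

    mac_centers = np.empty((spec.n_macrophages, 2))
    for i in range(spec.n_macrophages):
        for _ in range(max_tries):
            c = rng.uniform(r_mac, field - r_mac, 2)
            if i == 0 or np.all(
                np.linalg.norm(mac_centers[:i] - c, axis=1) > 4 * r_mac
            ):
                mac_centers[i] = c
                break
        else:
            raise PlacementError("could not place macrophages; enlarge field")

    # latent design: contact seeding is independent of shape; elongation is
    # drawn conditional on the contact flag via the log-odds shift
    base_logit = np.log(spec.base_elongation_prob / (1 - spec.base_elongation_prob))
    near_flags = (
        np.zeros(spec.n_tumor_cells, bool)
        if no_mac
        else rng.uniform(size=spec.n_tumor_cells) < spec.near_fraction
    )
    elongated = np.array([
        rng.uniform() < _sigmoid(base_logit + spec.association_strength * bool(nf))
        for nf in near_flags
    ])
    ratios = np.where(
        elongated,
        rng.uniform(*spec.elongated_axis_ratio, spec.n_tumor_cells),
        rng.uniform(*spec.round_axis_ratio, spec.n_tumor_cells),
    )
    semi_a = np.sqrt(spec.cell_area_um2 * ratios / np.pi)
    semi_b = np.sqrt(spec.cell_area_um2 / (ratios * np.pi))

    centers = np.empty((spec.n_tumor_cells, 2))
    placed_near = np.zeros(spec.n_tumor_cells, bool)
    mac_order = rng.permutation(spec.n_macrophages) if not no_mac else []
    near_rank = 0
    for i in range(spec.n_tumor_cells):
        margin = semi_a[i] + spec.pixel_size
        placed = False
        for attempt in range(max_tries):
            # near cells cycle through distinct macrophages; after half the
            # budget they fall back to uniform placement
            want_near = near_flags[i] and attempt < max_tries // 2
            if want_near:
                mc = mac_centers[
                    mac_order[(near_rank + attempt) % spec.n_macrophages]
                ]
                phi = rng.uniform(0, 2 * np.pi)
                rad = r_mac + rng.uniform(0.0, 2.0)
                c = mc + rad * np.array([np.cos(phi), np.sin(phi)])
                if not np.all((c > margin) & (c < field - margin)):
                    continue
            else:
                c = rng.uniform(margin, field - margin, 2)
            if i == 0 or np.all(
                np.linalg.norm(centers[:i] - c, axis=1)
                > 0.8 * (semi_a[:i] + semi_a[i])
            ):
                centers[i] = c
                placed_near[i] = want_near
                placed = True
                break
        if not placed:
            raise PlacementError("could not place tumor cells; enlarge field")
        if near_flags[i]:
            near_rank += 1
        if near_flags[i] and not placed_near[i]:
            # elongation conditions on realized contact: a near-intended cell
            # that fell back to uniform placement re-draws at the base rate;
            # its axis ratio is capped at the placement-time value so the
            # spacing check stays valid
            redraw = rng.uniform() < spec.base_elongation_prob
            new_ratio = (
                rng.uniform(*spec.elongated_axis_ratio)
                if redraw
                else rng.uniform(*spec.round_axis_ratio)
            )
            if new_ratio <= ratios[i]:
                elongated[i] = redraw
                ratios[i] = new_ratio
                semi_a[i] = np.sqrt(spec.cell_area_um2 * new_ratio / np.pi)
                semi_b[i] = np.sqrt(spec.cell_area_um2 / (new_ratio * np.pi))

    tumor = np.zeros((n_px, n_px), dtype=np.int32)
    records = []
    for i in range(spec.n_tumor_cells):
        angle = rng.uniform(-np.pi / 2, np.pi / 2)
        poly = _boundary_polygon(semi_a[i], semi_b[i], angle, 0.0, rng) + centers[i]
        rr, cc = draw.polygon(
            poly[:, 1] / spec.pixel_size, poly[:, 0] / spec.pixel_size,
            shape=tumor.shape,
        )
        # first-come rasterization: never overwrite an earlier cell
        free = tumor[rr, cc] == 0
        tumor[rr[free], cc[free]] = i + 1
        perim = ellipse_perimeter(semi_a[i], semi_b[i])
        area = np.pi * semi_a[i] * semi_b[i]
        if no_mac:
            dist = diag
        else:
            d_bnd = np.linalg.norm(
                poly[:, None, :] - mac_centers[None, :, :], axis=2
            ).min()
            dist = max(d_bnd - r_mac, 0.0)
        records.append(
            {
                "cell_id": i + 1,
                "true_distance_um": dist,
                "no_macrophage": no_mac,
                "seeded_near": bool(placed_near[i]),
                "elongated": bool(elongated[i]),
                "axis_ratio": ratios[i],
                "true_circularity": 4 * np.pi * area / perim**2,
            }
        )

    mac = np.zeros((n_px, n_px), dtype=np.int32)
    for i in range(spec.n_macrophages):
        rr, cc = draw.disk(
            (mac_centers[i, 1] / spec.pixel_size, mac_centers[i, 0] / spec.pixel_size),
            r_mac / spec.pixel_size,
            shape=mac.shape,
        )
        mac[rr, cc] = i + 1

    tumor_mask = LabeledMask(tumor, pixel_size=spec.pixel_size, role="tumor-cell")
    mac_mask = LabeledMask(mac, pixel_size=spec.pixel_size, role="macrophage")
    return tumor_mask, mac_mask, pd.DataFrame(records)
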