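"""Cell shape features, circularity binning, and macrophage proximity.

Shape features come from labeled masks: circularity 4*pi*A/P^2 with the
perimeter measured on a Gaussian-smoothed marching-squares contour (the raw
staircase contour overestimates smooth perimeters ~5%, biasing a rasterized
disk's circularity to ~0.90), plus eccentricity, extent, solidity,
convexity and axis lengths.  Proximity uses a distance transform of the macrophage mask;
enrichment of elongated cells near macrophages is tested by Pearson
chi-squared on the circularity-bin x contact-category table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats
from skimage import filters, measure
from sklearn.decomposition import PCA

from cometdyn.io import LabeledMask

#: contact categorization schemes in micrometres.  The seam between
#: "contact" (<5) and "nearby" (6-30) maps [5, 6) to nearby.
CONTACT_SCHEMES = {
    "invitro": [(5.0, "contact"), (30.0, "nearby"), (np.inf, "far")],
    "invivo": [(2.0, "proximal"), (np.inf, "distal")],
}

SHAPE_FEATURES = [
    "circularity",
    "eccentricity",
    "extent",
    "solidity",
    "convexity",
    "area_um2",
    "perimeter_um",
]


@dataclass
class BinSpec:
    """Half-open circularity bins [edge_i, edge_{i+1})."""

    edges: tuple = (0.0, 0.4, 0.7, 1.0)
    labels: tuple = ("low", "medium", "high")

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.labels) != len(e) - 1:
            raise ValueError("need one label per bin")


#: printed in-vivo preset: note the label order as published assigns "high"
#: to [0.7, 0.8) and "medium" to [0.8, 1.0) — an apparent label swap that is
#: reproduced verbatim here; pass your own labels to relabel.
IN_VITRO_BINS = BinSpec((0.0, 0.4, 0.7, 1.0), ("low", "medium", "high"))
IN_VIVO_BINS = BinSpec((0.0, 0.7, 0.8, 1.0), ("low", "high", "medium"))


def _perimeter(mask_bool: np.ndarray, sigma: float = 2.0) -> float:
    """Perimeter of the largest contour after closed-curve Gaussian smoothing.

    Smoothing (sigma in contour samples, wrapped) removes the rasterization
    staircase that inflates smooth perimeters; corners of genuinely
    polygonal shapes are rounded by O(sigma) pixels, a ~1-2 % effect.
    """
    # pad so objects touching the array edge still yield a closed contour
    mask_bool = np.pad(mask_bool, 1)
    contours = measure.find_contours(mask_bool.astype(float), 0.5)
    if not contours:
        return 0.0
    c = max(contours, key=len)
    if len(c) < 8:
        closed = np.vstack([c, c[:1]])
        return float(np.hypot(np.diff(closed[:, 0]),
                              np.diff(closed[:, 1])).sum())
    r = ndimage.gaussian_filter1d(c[:, 0], sigma, mode="wrap")
    col = ndimage.gaussian_filter1d(c[:, 1], sigma, mode="wrap")
    return float(
        np.hypot(np.diff(np.append(r, r[0])),
                 np.diff(np.append(col, col[0]))).sum()
    )


def shape_features_from_mask(mask: LabeledMask) -> pd.DataFrame:
    """One row of shape features per labeled object.

    Circularity above 1 by up to 0.05 (rasterization) is capped to 1 with
    ``capped=True``; objects under 16 pixels are flagged ``unreliable``.
    Convexity is convex-hull perimeter / perimeter (1 for convex shapes).
    """
    if mask.n_objects == 0:
        raise ValueError("mask has no labeled objects")
    ps = mask.pixel_size
    rows = []
    for props in measure.regionprops(mask.labels):
        cell = mask.labels == props.label
        perim_px = _perimeter(cell)
        area = props.area * ps**2
        perim = perim_px * ps
        circ = 4 * np.pi * area / perim**2 if perim > 0 else np.nan
        capped = False
        if circ > 1.0:
            if circ > 1.05:
                warnings.warn(
                    f"object {props.label}: circularity {circ:.3f} far above 1",
                    stacklevel=2,
                )
            circ, capped = 1.0, True
        hull_perim = _perimeter(props.image_convex) * ps
        convexity = hull_perim / perim if perim > 0 else np.nan
        rows.append(
            {
                "cell_id": props.label,
                "area_um2": area,
                "perimeter_um": perim,
                "circularity": circ,
                "circularity_capped": capped,
                "eccentricity": props.eccentricity,
                "extent": props.extent,
                "solidity": props.solidity,
                "convexity": min(convexity, 1.0) if np.isfinite(convexity) else np.nan,
                "major_axis_um": props.axis_major_length * ps,
                "minor_axis_um": props.axis_minor_length * ps,
                "centroid_x_um": props.centroid[1] * ps,
                "centroid_y_um": props.centroid[0] * ps,
                "unreliable": props.area < 16,
            }
        )
    return pd.DataFrame(rows)


def normalize_to_control(
    records: pd.DataFrame,
    control_condition: str,
    condition_col: str = "condition",
    value_col: str = "circularity",
) -> pd.DataFrame:
    """Z-score all conditions by the control condition's mean and SD."""
    ctrl = records.loc[records[condition_col] == control_condition, value_col]
    if len(ctrl) < 2:
        raise ValueError("control condition needs >= 2 cells")
    mu, sd = ctrl.mean(), ctrl.std(ddof=1)
    if sd == 0:
        raise ValueError("control condition has zero circularity SD")
    out = records.copy()
    out[f"{value_col}_norm"] = (out[value_col] - mu) / sd
    return out


def bin_by_circularity(
    records: pd.DataFrame,
    spec: BinSpec = IN_VITRO_BINS,
    value_col: str = "circularity",
) -> pd.DataFrame:
    """Assign half-open circularity bins on the unnormalized values.

    Values at or above the top edge (possible only through capping) fall in
    the top bin with ``bin_overflow=True``.
    """
    out = records.copy()
    edges = np.asarray(spec.edges, float)
    idx = np.searchsorted(edges, out[value_col].to_numpy(float), side="right") - 1
    overflow = idx >= len(spec.labels)
    idx = np.clip(idx, 0, len(spec.labels) - 1)
    out["circularity_bin"] = [spec.labels[i] for i in idx]
    out["bin_overflow"] = overflow
    return out


def nearest_macrophage_distance(
    tumor: LabeledMask, macrophage: LabeledMask
) -> pd.DataFrame:
    """Per tumor cell, the minimum distance (um) to the nearest macrophage.

    Built from the distance transform of the macrophage mask's complement:
    each tumor cell reports the minimum transform value over its own
    pixels; 0 means overlap or adjacency.  An empty macrophage mask yields
    +inf distances with ``no_macrophage=True``.
    """
    if tumor.labels.shape != macrophage.labels.shape:
        raise ValueError("masks must share the same pixel grid")
    no_mac = macrophage.n_objects == 0
    if no_mac:
        dt = np.full(tumor.labels.shape, np.inf)
    else:
        dt = ndimage.distance_transform_edt(macrophage.labels == 0) * tumor.pixel_size
    rows = []
    for cid in tumor.object_ids:
        cell = tumor.labels == cid
        rows.append(
            {
                "cell_id": int(cid),
                "nearest_macrophage_um": float(dt[cell].min()),
                "no_macrophage": no_mac,
            }
        )
    return pd.DataFrame(rows)


def contact_category(distance_um: float, scheme: str = "invitro") -> str:
    """Deterministic contact category for a distance (see CONTACT_SCHEMES)."""
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    for edge, label in CONTACT_SCHEMES[scheme]:
        if distance_um < edge:
            return label
    return CONTACT_SCHEMES[scheme][-1][1]


def proximity_enrichment(
    records: pd.DataFrame,
    bin_col: str = "circularity_bin",
    category_col: str = "contact_category",
    ratio_between: tuple = ("contact", "far"),
) -> dict:
    """Chi-squared independence test of circularity bin vs contact category.

    Returns the contingency table, the Pearson statistic and p (no
    continuity correction), and per-bin enrichment ratios
    P(contact) / P(far) within each bin.
    """
    table = pd.crosstab(records[bin_col], records[category_col])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 bins and >= 2 categories with members")
    chi2, p, dof, expected = sstats.chi2_contingency(table, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected count; merge sparse bins")
    near, far = ratio_between
    ratios = {}
    for b in table.index:
        n_near = table.loc[b, near] if near in table.columns else 0
        n_far = table.loc[b, far] if far in table.columns else 0
        ratios[b] = float(n_near / n_far) if n_far > 0 else np.inf
    return {
        "table": table,
        "chi2": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "enrichment_ratio": ratios,
    }


def group_compare(
    values: np.ndarray,
    group_labels: np.ndarray,
    batch_labels: np.ndarray | None = None,
    test: str = "t",
) -> dict:
    """Two-group comparison on batch means with Tukey-fence outlier exclusion.

    Batch means are computed per (group, batch); means outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of their group are excluded; a two-sided
    t or Mann-Whitney test runs on the surviving means.  With
    ``batch_labels=None`` the test runs on cell-level values directly.
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels)
    groups = pd.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("group_compare requires exactly 2 groups")

    excluded: dict = {g: [] for g in groups}
    samples = []
    if batch_labels is None:
        for g in groups:
            samples.append(values[group_labels == g])
    else:
        df = pd.DataFrame(
            {"v": values, "g": group_labels, "b": np.asarray(batch_labels)}
        )
        means = df.groupby(["g", "b"])["v"].mean().reset_index()
        for g in groups:
            m = means.loc[means["g"] == g, "v"].to_numpy()
            q1, q3 = np.percentile(m, [25, 75])
            iqr = q3 - q1
            keep = (m >= q1 - 1.5 * iqr) & (m <= q3 + 1.5 * iqr)
            excluded[g] = m[~keep].tolist()
            m = m[keep]
            if len(m) < 2:
                raise ValueError(f"group {g}: fewer than 2 batch means survive")
            samples.append(m)

    if test == "t":
        stat, p = sstats.ttest_ind(samples[0], samples[1])
    elif test == "mann_whitney":
        stat, p = sstats.mannwhitneyu(samples[0], samples[1],
                                      alternative="two-sided")
    else:
        raise ValueError("test must be 't' or 'mann_whitney'")
    return {
        "groups": list(groups),
        "group_means": [float(np.mean(s)) for s in samples],
        "excluded_batch_means": excluded,
        "statistic": float(stat),
        "p_value": float(p),
        "test": test,
    }


def mask_overlap_association(
    cells: LabeledMask, structure_image: np.ndarray
) -> pd.DataFrame:
    """Per-cell overlap with an Otsu-thresholded structure image.

    The structure channel (e.g. labeled vasculature) is binarized by Otsu's
    criterion; a cell is associated if any of its pixels overlaps the
    binary mask.  The fraction of associated cells is stored in
    ``df.attrs["fraction_associated"]``.
    """
    structure_image = np.asarray(structure_image, float)
    if structure_image.shape != cells.labels.shape:
        raise ValueError("images must share the same grid")
    if structure_image.max() == structure_image.min():
        raise ValueError("constant structure image: Otsu threshold undefined")
    thresh = filters.threshold_otsu(structure_image)
    binary = structure_image > thresh
    rows = [
        {"cell_id": int(cid), "associated": bool(binary[cells.labels == cid].any())}
        for cid in cells.object_ids
    ]
    df = pd.DataFrame(rows)
    df.attrs["otsu_threshold"] = float(thresh)
    df.attrs["fraction_associated"] = float(df["associated"].mean())
    return df


def elongation_score(
    records: pd.DataFrame,
    features: list[str] | None = None,
) -> pd.Series:
    """Combined shape score: PC1 of the z-scored shape features.

    The sign is fixed so a higher score means a more elongated cell
    (positive correlation with eccentricity).  Zero-variance features are
    dropped with a warning.
    """
    features = features or SHAPE_FEATURES
    if len(records) < 2:
        raise ValueError("need >= 2 cells")
    X = records[features].to_numpy(float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        dropped = [f for f, s in zip(features, sd) if s == 0]
        warnings.warn(f"dropping zero-variance shape feature(s): {dropped}",
                      stacklevel=2)
        features = [f for f, s in zip(features, sd) if s > 0]
        X = records[features].to_numpy(float)
        sd = X.std(axis=0)
    if len(features) < 2:
        raise ValueError("need >= 2 non-constant features")
    Xz = (X - X.mean(axis=0)) / sd
    scores = PCA(n_components=1).fit(Xz).transform(Xz)[:, 0]
    if "eccentricity" in records.columns:
        ecc = records["eccentricity"].to_numpy(float)
        if ecc.std() > 0 and np.corrcoef(scores, ecc)[0, 1] < 0:
            scores = -scores
    return pd.Series(scores, index=records.index, name="elongation_score")
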