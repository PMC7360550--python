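"""Cell-centroid migration rates and their shape/proximity correlates.

Migration speed is total centroid path length divided by elapsed time
(um/min); series shorter than four frames are rejected.  Correlations with
circularity and with nearest-macrophage distance are least-squares fits
with two-sided tests on the overall regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

MIN_FRAMES = 4


def migration_speed(
    times_min: np.ndarray, x_um: np.ndarray, y_um: np.ndarray,
    rule: str = "path",
) -> float:
    """Speed in um/min of one traced centroid series.

    ``rule="path"`` (default) divides the traced path length by elapsed
    time; ``rule="net"`` uses the net displacement instead.
    """
    t = np.asarray(times_min, float)
    x = np.asarray(x_um, float)
    y = np.asarray(y_um, float)
    if len(t) < MIN_FRAMES:
        raise ValueError(f"migration series needs >= {MIN_FRAMES} frames")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    elapsed = t[-1] - t[0]
    if rule == "path":
        dist = float(np.hypot(np.diff(x), np.diff(y)).sum())
    elif rule == "net":
        dist = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    else:
        raise ValueError("rule must be 'path' or 'net'")
    return dist / elapsed


def migration_table(
    centroids: pd.DataFrame, rule: str = "path"
) -> pd.DataFrame:
    """Per-cell migration speeds from a (cell_id, time_min, x, y) table.

    Cells traced for fewer than four frames are dropped and counted in
    ``df.attrs["n_rejected_short"]``.
    """
    rows, rejected = [], 0
    for cid, grp in centroids.sort_values("time_min").groupby("cell_id"):
        if len(grp) < MIN_FRAMES:
            rejected += 1
            continue
        rows.append(
            {
                "cell_id": int(cid),
                "n_frames": len(grp),
                "speed_um_per_min": migration_speed(
                    grp["time_min"], grp["x"], grp["y"], rule=rule
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_rejected_short"] = rejected
    return out


def speed_shape_correlation(
    speeds: np.ndarray,
    circularities: np.ndarray,
    fast_threshold: float = 0.25,
    low_circularity: float = 0.4,
) -> dict:
    """Regression of migration speed on circularity.

    Reports the least-squares slope, Pearson r, and the two-sided p of the
    overall regression, plus the fraction of fast cells (speed above
    ``fast_threshold`` um/min) with circularity <= ``low_circularity``.
    """
    s = np.asarray(speeds, float)
    c = np.asarray(circularities, float)
    if len(s) < 10:
        raise ValueError("need >= 10 cells")
    if s.std() == 0 or c.std() == 0:
        raise ValueError("zero variance in speed or circularity")
    fit = sstats.linregress(c, s)
    fast = s > fast_threshold
    frac = float((c[fast] <= low_circularity).mean()) if fast.any() else np.nan
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r": float(fit.rvalue),
        "p_value": float(fit.pvalue),
        "fraction_fast_low_circularity": frac,
        "n_fast": int(fast.sum()),
    }


def speed_vs_distance(
    speeds: np.ndarray,
    distances_um: np.ndarray,
    near_cutoff_um: float = 30.0,
) -> dict:
    """Speed vs nearest-macrophage distance: regression plus binned test.

    Pearson r with its two-sided test, and a near/far (cutoff in um)
    two-sided t test on the binned speeds.
    """
    s = np.asarray(speeds, float)
    d = np.asarray(distances_um, float)
    fit = sstats.linregress(d, s)
    near, far = s[d <= near_cutoff_um], s[d > near_cutoff_um]
    if len(near) < 2 or len(far) < 2:
        side = "near" if len(near) < 2 else "far"
        raise ValueError(f"{side} distance bin has < 2 cells")
    t_stat, t_p = sstats.ttest_ind(near, far)
    return {
        "pearson_r": float(fit.rvalue),
        "p_value": float(fit.pvalue),
        "slope": float(fit.slope),
        "near_mean": float(near.mean()),
        "far_mean": float(far.mean()),
        "binned_t": float(t_stat),
        "binned_p": float(t_p),
    }
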