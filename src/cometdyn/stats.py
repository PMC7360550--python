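"""Multivariate statistics over the track feature matrix.

Implements the study's statistics layer: per-feature variance-stabilizing
transforms and z-scoring, percentile/SD outlier removal, PCA with a fixed
sign convention, the two-feature (orientation + cellular coherence)
principal component, the cell-label permutation test with equal-cell
subsampling and Benjamini-Hochberg correction, Cohen's D in two pooled-SD
variants, histogram K-L divergence between PC1 distributions, clustergram
matrices, and the brightness-bias QC regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

#: default variance-stabilizing transform per feature; right-skewed
#: magnitudes get log, bounded axis distances sqrt, left-skewed bounded
#: features sqrt(1 - x), the rest pass through.
DEFAULT_TRANSFORMS: dict[str, str] = {
    "speed_avg": "log",
    "speed_min": "log",
    "speed_max": "log",
    "speed_sd": "log",
    "displacement": "log",
    "path_length": "log",
    "curvature": "log",
    "dist_major_norm": "sqrt",
    "dist_minor_norm": "sqrt",
    "orientation": "sqrt1m",
    "persistence": "sqrt1m",
    "dist_edge_norm": "none",
    "local_coherence": "none",
    "cellular_coherence": "none",
}


# ------------------------------------------------------------ transforms

def transform_and_scale(
    matrix: pd.DataFrame,
    transforms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Apply per-feature transforms then z-score each column to mean 0, SD 1.

    Only columns named in ``transforms`` (default :data:`DEFAULT_TRANSFORMS`
    restricted to present columns) are touched; label columns pass through.
    Non-positive values under ``log`` raise rather than being silently
    offset; a constant column raises (zero SD).
    """
    transforms = transforms or {
        k: v for k, v in DEFAULT_TRANSFORMS.items() if k in matrix.columns
    }
    out = matrix.copy()
    for feat, kind in transforms.items():
        col = out[feat].to_numpy(float)
        if kind == "log":
            if (col <= 0).any():
                bad = np.nonzero(col <= 0)[0][:5]
                raise ValueError(
                    f"log transform of '{feat}': non-positive values at rows "
                    f"{bad.tolist()}"
                )
            col = np.log(col)
        elif kind == "sqrt":
            if (col < 0).any():
                raise ValueError(f"sqrt transform of '{feat}': negative values")
            col = np.sqrt(col)
        elif kind == "sqrt1m":
            if (col > 1 + 1e-12).any():
                raise ValueError(f"sqrt(1-x) transform of '{feat}': values > 1")
            col = np.sqrt(np.clip(1.0 - col, 0.0, None))
        elif kind != "none":
            raise ValueError(f"unknown transform '{kind}' for '{feat}'")
        sd = col.std()
        if sd < 1e-12 * max(1.0, abs(col.mean())):
            raise ValueError(f"feature '{feat}' is constant; cannot z-score")
        out[feat] = (col - col.mean()) / sd
    return out


def remove_outlier_rows(
    matrix: pd.DataFrame,
    features: list[str],
    mode: str = "percentile_5_95",
) -> pd.DataFrame:
    """Drop rows with any selected feature outside the bounds.

    ``percentile_5_95`` keeps values within the [5th, 95th] percentile of
    each feature; ``sd3`` keeps values within mean +/- 3 SD.  Bounds are
    computed once on the input matrix, not iteratively.
    """
    if mode == "percentile_5_95":
        if len(matrix) < 20:
            raise ValueError("percentile outlier mode needs >= 20 rows")
        lo = matrix[features].quantile(0.05)
        hi = matrix[features].quantile(0.95)
    elif mode == "sd3":
        mu, sd = matrix[features].mean(), matrix[features].std(ddof=0)
        lo, hi = mu - 3 * sd, mu + 3 * sd
    else:
        raise ValueError("mode must be 'percentile_5_95' or 'sd3'")
    keep = ((matrix[features] >= lo) & (matrix[features] <= hi)).all(axis=1)
    if not keep.any():
        raise ValueError("outlier removal eliminated every row")
    return matrix.loc[keep].reset_index(drop=True)


# ------------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    loadings: pd.DataFrame            # feature x component
    scores: pd.DataFrame              # row x component (+ label columns)
    explained_variance_ratio: np.ndarray
    condition_means: pd.DataFrame | None = None  # mean +/- sem per condition


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    flipped = components.copy()
    for i in range(flipped.shape[0]):
        j = np.argmax(np.abs(flipped[i]))
        if flipped[i, j] < 0:
            flipped[i] = -flipped[i]
    return flipped


def fit_pca(
    matrix: pd.DataFrame,
    features: list[str],
    n_components: int = 2,
    condition_col: str | None = "condition",
) -> PcaResult:
    """PCA on already-scaled feature columns with a deterministic sign
    convention and per-condition mean score +/- s.e.m."""
    X = matrix[features].to_numpy(float)
    n_components = min(n_components, len(features), len(matrix))
    pca = PCA(n_components=n_components)
    pca.fit(X)
    comps = _fix_signs(pca.components_)
    scores = (X - X.mean(axis=0)) @ comps.T
    pc_names = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(comps.T, index=features, columns=pc_names)
    score_df = pd.DataFrame(scores, columns=pc_names, index=matrix.index)

    cond_means = None
    if condition_col is not None and condition_col in matrix.columns:
        score_df[condition_col] = matrix[condition_col].to_numpy()
        g = score_df.groupby(condition_col)[pc_names]
        cond_means = g.mean().join(g.sem(), lsuffix="_mean", rsuffix="_sem")
    return PcaResult(loadings, score_df, pca.explained_variance_ratio_, cond_means)


def two_feature_pc(
    matrix: pd.DataFrame,
    orientation_col: str = "orientation",
    coherence_col: str = "cellular_coherence",
) -> pd.DataFrame:
    """PC1 of the z-scored (orientation, cellular coherence) pair.

    The sign is fixed so higher orientation means higher PC1.  Returns the
    input labels plus a ``pc1`` column; explained variance is stored in
    ``df.attrs["explained_variance_ratio"]``.
    """
    for col in (orientation_col, coherence_col):
        if matrix[col].std() == 0:
            raise ValueError(f"feature '{col}' has zero variance")
    X = matrix[[orientation_col, coherence_col]].to_numpy(float)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0)
    pca = PCA(n_components=2).fit(Xz)
    w = pca.components_[0]
    scores = Xz @ w
    if np.corrcoef(scores, X[:, 0])[0, 1] < 0:
        scores = -scores
    out = matrix[[c for c in ("cell_id", "condition", "batch")
                  if c in matrix.columns]].copy()
    out["pc1"] = scores
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return out


def ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF support points and cumulative probabilities."""
    x = np.sort(np.asarray(values, float))
    return x, np.arange(1, len(x) + 1) / len(x)


# ------------------------------------------------- permutation testing

@dataclass
class PermutationResult:
    feature: str
    observed_p: float
    n_permutations: int
    n_smaller: int
    p_value: float
    q_value: float | None = None


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    return float(sstats.ranksums(a, b).pvalue)


def permutation_test(
    values: np.ndarray,
    cell_ids: np.ndarray,
    group_labels: np.ndarray,
    n_permutations: int = 1000,
    subsample_cells: int | None = None,
    max_tracks_per_cell: int | None = 25,
    rng: np.random.Generator | None = None,
    comparison: str = "strict",
    feature: str = "feature",
) -> PermutationResult:
    """Cell-label permutation test on track-level values.

    The observed two-sided Wilcoxon rank-sum p is computed on track values
    pooled by group; each permutation reassigns whole cells between the two
    groups (preserving group cell counts) and recomputes the rank-sum p.
    The final p is the fraction of permutations with a smaller p than the
    observed one (``comparison="le"`` counts ties), floored at
    1/n_permutations.  Equal-cell and per-cell track subsampling, when
    requested, are drawn once before testing.
    """
    rng = rng or np.random.default_rng()
    values = np.asarray(values, float)
    cell_ids = np.asarray(cell_ids)
    group_labels = np.asarray(group_labels)

    cells = pd.DataFrame(
        {"cell": cell_ids, "group": group_labels}
    ).drop_duplicates()
    if cells["cell"].duplicated().any():
        raise ValueError("a cell appears in more than one group")
    groups = cells["group"].unique()
    if len(groups) != 2:
        raise ValueError("permutation test requires exactly 2 groups")
    per_group = cells.groupby("group")["cell"].apply(list)
    if any(len(c) < 2 for c in per_group):
        raise ValueError("each group needs >= 2 cells to permute")

    # one-shot subsampling: equal cells per group, then <= max tracks/cell
    selected_cells = []
    for g in groups:
        cand = per_group[g]
        if subsample_cells is not None:
            if subsample_cells > len(cand):
                raise ValueError(
                    f"group {g} has {len(cand)} cells < subsample {subsample_cells}"
                )
            cand = list(rng.choice(cand, subsample_cells, replace=False))
        selected_cells.extend(cand)
    keep = np.isin(cell_ids, selected_cells)
    if max_tracks_per_cell is not None:
        idx = []
        for c in selected_cells:
            rows = np.nonzero(keep & (cell_ids == c))[0]
            if len(rows) > max_tracks_per_cell:
                rows = rng.choice(rows, max_tracks_per_cell, replace=False)
            idx.extend(rows)
        idx = np.sort(np.asarray(idx))
    else:
        idx = np.nonzero(keep)[0]

    vals = values[idx]
    cids = cell_ids[idx]
    cell_to_group = dict(zip(cells["cell"], cells["group"]))
    grp = np.array([cell_to_group[c] for c in cids])

    obs_p = _ranksum_p(vals[grp == groups[0]], vals[grp == groups[1]])

    uniq_cells = np.unique(cids)
    n_first = sum(1 for c in uniq_cells if cell_to_group[c] == groups[0])
    cell_vals = {c: vals[cids == c] for c in uniq_cells}

    n_smaller = 0
    for _ in range(n_permutations):
        perm = rng.permutation(uniq_cells)
        a = np.concatenate([cell_vals[c] for c in perm[:n_first]])
        b = np.concatenate([cell_vals[c] for c in perm[n_first:]])
        p = _ranksum_p(a, b)
        if (p < obs_p) if comparison == "strict" else (p <= obs_p):
            n_smaller += 1

    p_final = max(n_smaller / n_permutations, 1.0 / n_permutations)
    return PermutationResult(feature, obs_p, n_permutations, n_smaller, p_final)


def permutation_test_features(
    matrix: pd.DataFrame,
    features: list[str],
    group_col: str = "condition",
    cell_col: str = "cell_id",
    bh_q: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Run the permutation test per feature and BH-adjust across the family."""
    results = [
        permutation_test(
            matrix[f].to_numpy(),
            matrix[cell_col].to_numpy(),
            matrix[group_col].to_numpy(),
            feature=f,
            **kwargs,
        )
        for f in features
    ]
    pvals = [r.p_value for r in results]
    _, qvals, _, _ = multipletests(pvals, alpha=bh_q, method="fdr_bh")
    rows = []
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------- effect sizes

@dataclass
class EffectSize:
    feature: str
    mean_1: float
    mean_2: float
    var_1: float
    var_2: float
    sd_pooled: float
    d: float
    variant: str
    per_batch_d: list[float] = field(default_factory=list)

    @property
    def batch_mean_d(self) -> float:
        return float(np.mean(self.per_batch_d)) if self.per_batch_d else self.d


def cohens_d(
    values_1: np.ndarray,
    values_2: np.ndarray,
    variant: str = "as_printed",
    feature: str = "feature",
) -> EffectSize:
    """Cohen's D = (mu1 - mu2) / SD_pooled in two pooled-SD variants.

    ``as_printed`` uses SD_pooled = sqrt(Var1 + Var2) / 2 (the form used in
    the original analysis); ``classic`` uses sqrt((Var1 + Var2) / 2).  The
    two differ by the exact factor sqrt(2): d_printed = sqrt(2) d_classic.
    """
    v1 = np.asarray(values_1, float)
    v2 = np.asarray(values_2, float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs >= 2 values")
    m1, m2 = v1.mean(), v2.mean()
    var1, var2 = v1.var(ddof=1), v2.var(ddof=1)
    if variant == "as_printed":
        sd_pooled = np.sqrt(var1 + var2) / 2
    elif variant == "classic":
        sd_pooled = np.sqrt((var1 + var2) / 2)
    else:
        raise ValueError("variant must be 'as_printed' or 'classic'")
    if sd_pooled == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    return EffectSize(
        feature, float(m1), float(m2), float(var1), float(var2),
        float(sd_pooled), float((m1 - m2) / sd_pooled), variant,
    )


def cohens_d_batched(
    matrix: pd.DataFrame,
    feature: str,
    group_col: str = "condition",
    batch_col: str = "batch",
    variant: str = "as_printed",
) -> EffectSize:
    """Per-batch Cohen's D averaged across batches (batch-effect control)."""
    groups = matrix[group_col].unique()
    if len(groups) != 2:
        raise ValueError("effect size requires exactly 2 groups")
    pooled = cohens_d(
        matrix.loc[matrix[group_col] == groups[0], feature],
        matrix.loc[matrix[group_col] == groups[1], feature],
        variant=variant,
        feature=feature,
    )
    per_batch = []
    for _, sub in matrix.groupby(batch_col):
        if sub[group_col].nunique() != 2:
            continue
        if (sub.groupby(group_col)[feature].count() < 2).any():
            continue
        per_batch.append(
            cohens_d(
                sub.loc[sub[group_col] == groups[0], feature],
                sub.loc[sub[group_col] == groups[1], feature],
                variant=variant,
                feature=feature,
            ).d
        )
    pooled.per_batch_d = per_batch
    return pooled


# ------------------------------------------------------------- divergence

def kl_divergence(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    bins: int = 50,
) -> dict[str, float]:
    """Histogram K-L divergence D(A||B) between two score samples.

    Both samples are binned on a shared support spanning their pooled
    range; one pseudo-count per bin regularizes empty bins.  Returns the
    asymmetric divergence both ways and their symmetrized mean (nats).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        raise ValueError("degenerate samples: zero pooled range")
    edges = np.linspace(lo, hi, bins + 1)
    pa = np.histogram(a, bins=edges)[0] + 1.0
    pb = np.histogram(b, bins=edges)[0] + 1.0
    pa /= pa.sum()
    pb /= pb.sum()
    d_ab = float(np.sum(pa * np.log(pa / pb)))
    d_ba = float(np.sum(pb * np.log(pb / pa)))
    return {"kl_ab": d_ab, "kl_ba": d_ba, "kl_sym": 0.5 * (d_ab + d_ba)}


# ------------------------------------------------------------ clustergram

def clustergram_matrix(
    matrix: pd.DataFrame,
    features: list[str],
    condition_col: str = "condition",
):
    """Condition x feature means with complete-linkage Euclidean dendrograms.

    Tracks with any plotted feature beyond 3 SD are removed first; condition
    means are computed and each feature column z-scored.  Returns the table
    and (row_linkage, col_linkage) from :mod:`scipy.cluster.hierarchy`.
    """
    if matrix[condition_col].nunique() < 2:
        raise ValueError("clustergram needs >= 2 conditions")
    trimmed = remove_outlier_rows(matrix, features, mode="sd3")
    means = trimmed.groupby(condition_col)[features].mean()
    sd = means.std(ddof=0)
    if (sd == 0).any():
        sd = sd.replace(0, 1.0)
    z = (means - means.mean()) / sd
    row_link = hierarchy.linkage(z.to_numpy(), method="complete", metric="euclidean")
    col_link = hierarchy.linkage(z.to_numpy().T, method="complete",
                                 metric="euclidean")
    return z, row_link, col_link


# ------------------------------------------------------------ bias QC

def expression_bias_qc(
    cell_feature_means: pd.DataFrame,
    brightness: np.ndarray,
    mean_track_duration: np.ndarray,
) -> pd.DataFrame:
    """Per-feature R^2 against cell brightness, raw and duration-adjusted.

    Raw R^2 is the squared Pearson correlation of each cell-mean feature
    with brightness; the adjusted value correlates the residuals of both
    after regressing each on mean track duration, exposing whether any
    brightness association is mediated by track duration.
    """
    if len(cell_feature_means) < 10:
        raise ValueError("need >= 10 cells")
    b = np.asarray(brightness, float)
    dur = np.asarray(mean_track_duration, float)
    if b.std() == 0:
        raise ValueError("constant brightness")

    def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    b_res = _residualize(b, dur)
    rows = []
    for feat in cell_feature_means.columns:
        y = cell_feature_means[feat].to_numpy(float)
        r_raw = np.corrcoef(y, b)[0, 1] if y.std() > 0 else 0.0
        y_res = _residualize(y, dur)
        if y_res.std() > 0 and b_res.std() > 0:
            r_adj = np.corrcoef(y_res, b_res)[0, 1]
        else:
            r_adj = 0.0
        rows.append(
            {"feature": feat, "r2_raw": r_raw**2, "r2_duration_adjusted": r_adj**2}
        )
    return pd.DataFrame(rows)
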