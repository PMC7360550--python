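"""Transforms, PCA, permutation testing, effect sizes, divergence."""

import numpy as np
import pandas as pd
import pytest

from cometdyn.stats import (
    DEFAULT_TRANSFORMS,
    cohens_d,
    cohens_d_batched,
    clustergram_matrix,
    expression_bias_qc,
    fit_pca,
    kl_divergence,
    permutation_test,
    permutation_test_features,
    remove_outlier_rows,
    transform_and_scale,
    two_feature_pc,
)


# ------------------------------------------------------------ transforms

def test_transform_and_scale_contract():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "speed_avg": rng.lognormal(0, 0.3, 500),
            "orientation": rng.uniform(0, 1, 500),
            "cellular_coherence": rng.uniform(-1, 1, 500),
        }
    )
    out = transform_and_scale(df)
    for col in df.columns:
        assert abs(out[col].mean()) < 1e-10
        assert out[col].to_numpy().std() == pytest.approx(1.0, abs=1e-10)


def test_sqrt1m_maps_orientation_one_to_minimum():
    # sqrt(1 - x) sends x = 1 to 0 before scaling, so the z-scored value of
    # a perfectly axis-aligned track is the column minimum
    df = pd.DataFrame({"orientation": [1.0, 0.5, 0.2, 0.8, 0.0]})
    out = transform_and_scale(df, {"orientation": "sqrt1m"})
    assert out["orientation"].idxmin() == 0


def test_log_transform_rejects_nonpositive_naming_feature():
    df = pd.DataFrame({"curvature": [1.0, 0.0, 2.0]})
    with pytest.raises(ValueError, match="curvature"):
        transform_and_scale(df, {"curvature": "log"})


def test_constant_column_rejected():
    df = pd.DataFrame({"persistence": [0.8] * 10})
    with pytest.raises(ValueError, match="constant"):
        transform_and_scale(df, {"persistence": "sqrt1m"})


def test_percentile_outlier_removal_survival_rate():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"f": rng.normal(0, 1, 10_000)})
    kept = remove_outlier_rows(df, ["f"], mode="percentile_5_95")
    assert len(kept) / len(df) == pytest.approx(0.90, abs=0.02)


def test_sd3_mode_keeps_bounded_data():
    df = pd.DataFrame({"f": np.linspace(-1, 1, 100)})
    assert len(remove_outlier_rows(df, ["f"], mode="sd3")) == 100


def test_joint_survival_below_marginals():
    rng = np.random.default_rng(2)
    df = pd.DataFrame({"a": rng.normal(0, 1, 5000), "b": rng.normal(0, 1, 5000)})
    joint = len(remove_outlier_rows(df, ["a", "b"]))
    for col in ("a", "b"):
        assert joint <= len(remove_outlier_rows(df, [col]))


# ------------------------------------------------------------------- PCA

def test_pca_recovers_planted_factor_subspace():
    rng = np.random.default_rng(3)
    n, p = 10_000, 6
    u1 = np.array([1, 1, 0, 0, 0, 0]) / np.sqrt(2)
    u2 = np.array([0, 0, 1, -1, 0, 0]) / np.sqrt(2)
    X = (
        np.outer(rng.normal(0, 3, n), u1)
        + np.outer(rng.normal(0, 2, n), u2)
        + rng.normal(0, 0.3, (n, p))
    )
    cols = [f"f{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    res = fit_pca(df, cols, n_components=2, condition_col=None)
    W = res.loadings.to_numpy()  # p x 2
    basis = np.column_stack([u1, u2])
    # principal angles between recovered and true subspaces
    sv = np.linalg.svd(basis.T @ W, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(sv, -1, 1)))
    assert np.all(angles < 5.0)


def test_isotropic_noise_has_flat_spectrum():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(0, 1, (10_000, 5)),
                      columns=list("abcde"))
    res = fit_pca(df, list("abcde"), n_components=5, condition_col=None)
    ev = res.explained_variance_ratio
    assert ev.max() / ev.min() < 1.5


def test_duplicated_dataset_gives_identical_loadings():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(0, 1, (200, 4)), columns=list("abcd"))
    doubled = pd.concat([df, df], ignore_index=True)
    r1 = fit_pca(df, list("abcd"), condition_col=None)
    r2 = fit_pca(doubled, list("abcd"), condition_col=None)
    pd.testing.assert_frame_equal(r1.loadings, r2.loadings)


def test_two_feature_pc_perfect_correlation_and_sign():
    rng = np.random.default_rng(6)
    ori = rng.uniform(0, 1, 300)
    df = pd.DataFrame(
        {"orientation": ori, "cellular_coherence": 2 * ori - 1,
         "condition": "x"}
    )
    out = two_feature_pc(df)
    assert out.attrs["explained_variance_ratio"][0] == pytest.approx(1.0)
    assert np.corrcoef(out["pc1"], ori)[0, 1] > 0.999


def test_two_feature_pc_cdf_dominance_by_construction():
    rng = np.random.default_rng(7)
    n = 400
    a = pd.DataFrame(
        {"orientation": rng.beta(6, 2, n),
         "cellular_coherence": rng.uniform(0.3, 0.9, n), "condition": "A"}
    )
    b = pd.DataFrame(
        {"orientation": rng.beta(2, 6, n),
         "cellular_coherence": rng.uniform(-0.5, 0.2, n), "condition": "B"}
    )
    out = two_feature_pc(pd.concat([a, b], ignore_index=True))
    qa = np.quantile(out.loc[out.condition == "A", "pc1"], [0.25, 0.5, 0.75])
    qb = np.quantile(out.loc[out.condition == "B", "pc1"], [0.25, 0.5, 0.75])
    assert np.all(qa > qb)

    with pytest.raises(ValueError, match="zero variance"):
        two_feature_pc(
            pd.DataFrame({"orientation": [0.5] * 5,
                          "cellular_coherence": [0.1, 0.2, 0.3, 0.4, 0.5]})
        )


# ------------------------------------------------- permutation testing

def _grouped_data(rng, n_cells=10, tracks=20, shift=0.0):
    cells = np.repeat(np.arange(n_cells), tracks)
    grp = np.where(cells < n_cells // 2, "A", "B")
    vals = rng.normal(0, 1, len(cells)) + np.where(grp == "A", shift, 0.0)
    return vals, cells, grp


def test_permutation_floor_when_no_permutation_beats_observed():
    rng = np.random.default_rng(8)
    vals, cells, grp = _grouped_data(rng, shift=5.0)
    res = permutation_test(vals, cells, grp, n_permutations=1000,
                           rng=np.random.default_rng(0))
    assert res.p_value == pytest.approx(0.001)


def test_permutation_symmetric_under_label_swap():
    rng = np.random.default_rng(9)
    vals, cells, grp = _grouped_data(rng, shift=0.8)
    swapped = np.where(grp == "A", "B", "A")
    r1 = permutation_test(vals, cells, grp, n_permutations=200,
                          rng=np.random.default_rng(1))
    r2 = permutation_test(vals, cells, swapped, n_permutations=200,
                          rng=np.random.default_rng(1))
    assert r1.observed_p == pytest.approx(r2.observed_p)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_permutation_requires_two_cells_per_group():
    vals = np.arange(10.0)
    cells = np.array([1] * 5 + [2] * 5)
    grp = np.array(["A"] * 5 + ["B"] * 5)
    with pytest.raises(ValueError, match=">= 2 cells"):
        permutation_test(vals, cells, grp, n_permutations=10)


def test_subsampling_caps_cells_and_tracks():
    rng = np.random.default_rng(10)
    vals, cells, grp = _grouped_data(rng, n_cells=12, tracks=40)
    res = permutation_test(
        vals, cells, grp, n_permutations=50, subsample_cells=4,
        max_tracks_per_cell=10, rng=np.random.default_rng(2),
    )
    assert res.n_permutations == 50


def test_bh_adjustment_across_feature_family():
    rng = np.random.default_rng(11)
    cells = np.repeat(np.arange(8), 15)
    grp = np.where(cells < 4, "A", "B")
    df = pd.DataFrame(
        {
            "cell_id": cells,
            "condition": grp,
            "null_feat": rng.normal(0, 1, len(cells)),
            "shifted_feat": rng.normal(0, 1, len(cells))
            + np.where(grp == "A", 3.0, 0.0),
        }
    )
    out = permutation_test_features(
        df, ["null_feat", "shifted_feat"], n_permutations=100,
        max_tracks_per_cell=None, rng=np.random.default_rng(3),
    )
    assert set(out["feature"]) == {"null_feat", "shifted_feat"}
    assert (out["q_value"] >= out["p_value"] - 1e-12).all()


# ---------------------------------------------------------- effect sizes

def test_cohens_d_zero_for_equal_means():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert cohens_d(v, v.copy()).d == pytest.approx(0.0)


def test_cohens_d_variant_identity_holds_exactly():
    rng = np.random.default_rng(12)
    for _ in range(20):
        a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 30)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 25)
        dp = cohens_d(a, b, "as_printed").d
        dc = cohens_d(a, b, "classic").d
        assert dp == pytest.approx(np.sqrt(2) * dc, abs=1e-12)


def test_cohens_d_gaussian_limit():
    rng = np.random.default_rng(13)
    a = rng.normal(1, 1, 200_000)
    b = rng.normal(0, 1, 200_000)
    assert cohens_d(a, b, "classic").d == pytest.approx(1.0, abs=0.02)
    assert cohens_d(a, b, "as_printed").d == pytest.approx(np.sqrt(2), abs=0.03)


def test_batched_d_equals_pooled_for_identical_batches():
    rng = np.random.default_rng(14)
    base = pd.DataFrame(
        {
            "condition": ["A"] * 20 + ["B"] * 20,
            "f": np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)]),
        }
    )
    two = pd.concat(
        [base.assign(batch="b1"), base.assign(batch="b2")], ignore_index=True
    )
    es = cohens_d_batched(two, "f")
    single = cohens_d(
        base.loc[base.condition == "A", "f"],
        base.loc[base.condition == "B", "f"],
    )
    assert es.batch_mean_d == pytest.approx(single.d)


# ------------------------------------------------------------- divergence

def test_kl_self_divergence_zero_and_nonnegative():
    rng = np.random.default_rng(15)
    a = rng.normal(0, 1, 2000)
    assert kl_divergence(a, a)["kl_ab"] == pytest.approx(0.0, abs=1e-12)
    b = rng.normal(0.5, 1.5, 2000)
    assert kl_divergence(a, b)["kl_ab"] >= 0
    assert kl_divergence(b, a)["kl_ab"] >= 0


def test_kl_gaussian_closed_form():
    rng = np.random.default_rng(16)
    a = rng.normal(0, 1, 100_000)
    b = rng.normal(1, 1, 100_000)
    assert kl_divergence(a, b)["kl_ab"] == pytest.approx(0.5, rel=0.15)


def test_kl_invariant_to_common_affine_rescaling():
    rng = np.random.default_rng(17)
    a = rng.normal(0, 1, 5000)
    b = rng.normal(1, 2, 5000)
    d0 = kl_divergence(a, b)["kl_ab"]
    d1 = kl_divergence(3 * a + 7, 3 * b + 7)["kl_ab"]
    assert d1 == pytest.approx(d0, abs=1e-12)


# ------------------------------------------------------------ clustergram

def _condition_frame(rng, cond, mu, n=200):
    return pd.DataFrame(
        {
            "condition": cond,
            "f1": rng.normal(mu, 1, n),
            "f2": rng.normal(-mu, 1, n),
            "f3": rng.normal(0, 1, n),
        }
    )


def test_clustergram_similar_conditions_merge_first():
    rng = np.random.default_rng(18)
    df = pd.concat(
        [
            _condition_frame(rng, "near1", 0.0),
            _condition_frame(rng, "near2", 0.1),
            _condition_frame(rng, "distant", 4.0),
        ],
        ignore_index=True,
    )
    z, row_link, _ = clustergram_matrix(df, ["f1", "f2", "f3"])
    assert abs(z.mean()).max() < 1e-10
    # the first merge joins the two near conditions
    first = sorted(row_link[0, :2].astype(int))
    names = list(z.index)
    assert {names[first[0]], names[first[1]]} == {"near1", "near2"}


def test_clustergram_requires_two_conditions():
    rng = np.random.default_rng(19)
    df = _condition_frame(rng, "only", 0.0)
    with pytest.raises(ValueError, match="2 conditions"):
        clustergram_matrix(df, ["f1", "f2"])


# ------------------------------------------------------------ bias QC

def test_bias_qc_identity_feature_scores_r2_one():
    rng = np.random.default_rng(20)
    b = rng.uniform(100, 500, 50)
    dur = rng.uniform(3, 10, 50)
    feats = pd.DataFrame({"copy_of_brightness": b,
                          "indep": rng.normal(0, 1, 50)})
    out = expression_bias_qc(feats, b, dur).set_index("feature")
    assert out.loc["copy_of_brightness", "r2_raw"] == pytest.approx(1.0)
    assert out.loc["indep", "r2_raw"] < 0.2


def test_bias_qc_duration_mediation_reduces_r2():
    rng = np.random.default_rng(21)
    n = 200
    dur = rng.uniform(3, 10, n)
    b = 50 * dur + rng.normal(0, 5, n)       # brightness driven by duration
    feat = 2 * dur + rng.normal(0, 0.5, n)   # feature driven by duration
    out = expression_bias_qc(pd.DataFrame({"f": feat}), b, dur)
    assert out.loc[0, "r2_duration_adjusted"] < out.loc[0, "r2_raw"]
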