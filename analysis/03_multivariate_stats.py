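#!/usr/bin/env python
"""Statistics over the feature table: PCA, permutation tests, effect
sizes, the two-feature coherence/orientation PC, and K-L divergence.

Consumes results/features.csv from 02 and writes tidy tables under
results/: transformed PCA loadings and condition scores, per-feature
permutation p/q values, per-feature effect sizes (printed-variant Cohen's
D), the two-feature PC1 scores per condition, and their K-L divergence.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cometdyn.config import RunConfig
from cometdyn.features import FEATURE_COLUMNS
from cometdyn.stats import (
    cohens_d_batched,
    fit_pca,
    kl_divergence,
    permutation_test_features,
    remove_outlier_rows,
    transform_and_scale,
    two_feature_pc,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = RunConfig(n_permutations=1000, seed=0)
    features = pd.read_csv(ROOT / "features.csv")
    conds = sorted(features["condition"].unique())

    trimmed = remove_outlier_rows(features, FEATURE_COLUMNS,
                                  mode="percentile_5_95")
    print(f"outlier removal: {len(features)} -> {len(trimmed)} tracks")
    scaled = transform_and_scale(trimmed)
    pca = fit_pca(scaled, FEATURE_COLUMNS, n_components=2)
    pca.loadings.to_csv(ROOT / "pca_loadings.csv")
    pca.condition_means.to_csv(ROOT / "pca_condition_scores.csv")
    print("PC1/PC2 explained variance: "
          f"{np.round(pca.explained_variance_ratio[:2], 3)}")

    features["cell_uid"] = (
        features["condition"] + "/" + features["cell_id"].astype(str)
    )
    perm = permutation_test_features(
        features, FEATURE_COLUMNS, cell_col="cell_uid",
        n_permutations=config.n_permutations,
        max_tracks_per_cell=config.max_tracks_per_cell,
        rng=config.rng("permutation_test"),
    )
    perm.to_csv(ROOT / "permutation_tests.csv", index=False)
    sig = perm[perm.q_value < 0.05]["feature"].tolist()
    print(f"features significant after BH (q < 0.05): {sig}")

    rows = []
    for feat in FEATURE_COLUMNS:
        es = cohens_d_batched(features, feat, group_col="condition")
        rows.append({"feature": feat, "d_printed": es.d,
                     "batch_mean_d": es.batch_mean_d})
    es_table = pd.DataFrame(rows).sort_values("d_printed")
    es_table.to_csv(ROOT / "effect_sizes.csv", index=False)
    top = es_table.iloc[[0, -1]]["feature"].tolist()
    print(f"largest effect sizes: {top}")

    pc = two_feature_pc(features)
    pc.to_csv(ROOT / "two_feature_pc.csv", index=False)
    a = pc.loc[pc.condition == conds[0], "pc1"]
    b = pc.loc[pc.condition == conds[1], "pc1"]
    kl = kl_divergence(a, b)
    pd.DataFrame([kl]).to_csv(ROOT / "kl_divergence.csv", index=False)
    print(f"two-feature PC1: KL({conds[0]}||{conds[1]}) = {kl['kl_ab']:.3f}")


if __name__ == "__main__":
    main()
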