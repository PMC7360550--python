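#!/usr/bin/env python
"""Migration rates and their correlation with cell shape and macrophage
distance, on the synthetic centroid series from 01."""

from pathlib import Path

import pandas as pd

from cometdyn.migration import (
    migration_table,
    speed_shape_correlation,
    speed_vs_distance,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cent = pd.read_csv(ROOT / "synthetic" / "migration_centroids.csv")
    gt = pd.read_csv(ROOT / "synthetic" / "migration_ground_truth.csv")
    table = migration_table(cent).merge(gt, on="cell_id")
    table.to_csv(ROOT / "migration.csv", index=False)
    print(f"{len(table)} cells; mean rate "
          f"{table.speed_um_per_min.mean():.3f} um/min")

    shape_corr = speed_shape_correlation(table["speed_um_per_min"],
                                         table["circularity"])
    pd.DataFrame([shape_corr]).to_csv(ROOT / "migration_speed_shape.csv",
                                      index=False)
    print(f"speed ~ circularity: slope {shape_corr['slope']:.3f}, "
          f"r = {shape_corr['pearson_r']:.2f}, p = {shape_corr['p_value']:.2g}")

    dist = speed_vs_distance(table["speed_um_per_min"],
                             table["nearest_tam_distance_um"])
    pd.DataFrame([dist]).to_csv(ROOT / "migration_speed_distance.csv",
                                index=False)
    print(f"speed ~ macrophage distance: r = {dist['pearson_r']:.2f} "
          f"(binned t-test p = {dist['binned_p']:.2g})")


if __name__ == "__main__":
    main()
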