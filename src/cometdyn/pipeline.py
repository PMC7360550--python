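"""End-to-end pipeline: track tables + masks in, tidy result tables out.

``run_pipeline`` is a pure function of (inputs, config): it ingests one or
more (condition, batch) datasets, filters tracks, computes the 14-feature
table, and — when two or more conditions are present — runs the
transform/PCA and permutation/effect-size statistics.  Everything is
written as CSV plus a JSON run log echoing the config and version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

import cometdyn
from cometdyn import stats as cstats
from cometdyn.config import RunConfig
from cometdyn.features import FEATURE_COLUMNS, compute_feature_table, filter_tracks
from cometdyn.geometry import geometries_for_mask
from cometdyn.io import read_label_mask, read_track_table

logger = logging.getLogger("cometdyn")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class DatasetInput:
    """One (condition, batch) dataset on disk."""

    tracks: str
    mask: str
    pixel_size: float
    frame_interval: float
    condition: str = ""
    batch: str = ""
    coordinate_unit: str = "pixel"


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


@_stage("read_track_table")
def _read_tracks(ds: DatasetInput):
    return read_track_table(
        ds.tracks, ds.pixel_size, ds.frame_interval,
        coordinate_unit=ds.coordinate_unit,
    )


@_stage("read_label_mask")
def _read_mask(ds: DatasetInput):
    return read_label_mask(ds.mask, ds.pixel_size)


def run_pipeline(
    config: RunConfig,
    inputs: list[DatasetInput],
    out_dir: str | Path,
) -> dict:
    """Run ingestion -> filters -> features -> statistics and write results.

    Writes ``features.csv``, ``rejections.csv``, ``cell_summary.csv`` and,
    for two-condition runs, ``permutation_tests.csv`` and
    ``effect_sizes.csv``, plus ``run_log.json``.  Returns the result tables
    in memory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    feature_frames, rejection_frames = [], []
    for ds in inputs:
        table = _read_tracks(ds)
        mask = _read_mask(ds)
        geoms = geometries_for_mask(mask)
        filtered, report = filter_tracks(table, geoms, config)
        report["condition"], report["batch"] = ds.condition, ds.batch
        rejection_frames.append(report)
        feats = compute_feature_table(
            filtered, geoms, config, condition=ds.condition, batch=ds.batch
        )
        feature_frames.append(feats)

    features = pd.concat(feature_frames, ignore_index=True)
    rejections = pd.concat(rejection_frames, ignore_index=True)
    # per-condition offsets keep cell ids unique across datasets
    features["cell_uid"] = (
        features["condition"].astype(str) + "/" + features["batch"].astype(str)
        + "/" + features["cell_id"].astype(str)
    )

    cell_summary = (
        features.groupby(["condition", "batch", "cell_id"])[FEATURE_COLUMNS]
        .mean()
        .reset_index()
    )

    results: dict = {
        "features": features,
        "rejections": rejections,
        "cell_summary": cell_summary,
    }

    conditions = features["condition"].unique()
    if len(conditions) == 2 and len(features) > 0:
        rng = config.rng("permutation_test")
        try:
            perm = cstats.permutation_test_features(
                features,
                FEATURE_COLUMNS,
                group_col="condition",
                cell_col="cell_uid",
                bh_q=config.bh_q,
                n_permutations=config.n_permutations,
                subsample_cells=config.subsample_cells,
                max_tracks_per_cell=config.max_tracks_per_cell,
                rng=rng,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("permutation_test", exc) from exc
        effect_rows = []
        for feat in FEATURE_COLUMNS:
            es = cstats.cohens_d_batched(features, feat, group_col="condition")
            effect_rows.append(
                {
                    "feature": feat,
                    "d": es.d,
                    "batch_mean_d": es.batch_mean_d,
                    "variant": es.variant,
                }
            )
        results["permutation_tests"] = perm
        results["effect_sizes"] = pd.DataFrame(effect_rows)

    for name in ("features", "rejections", "cell_summary",
                 "permutation_tests", "effect_sizes"):
        if name in results:
            results[name].to_csv(out_dir / f"{name}.csv", index=False)

    log = {
        "version": cometdyn.__version__,
        "config": config.to_dict(),
        "inputs": [vars(ds) for ds in inputs],
        "n_tracks": int(features["track_id"].nunique()) if len(features) else 0,
        "n_feature_columns": len(FEATURE_COLUMNS),
        "conditions": sorted(map(str, conditions)),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["run_log"] = log
    return results
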