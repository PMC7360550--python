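"""Run configuration for the comet-dynamics pipeline.

All thresholds, bin edges, resampling counts and the master random seed live
in a single :class:`RunConfig` so a run is a pure function of (inputs,
config).  The config round-trips through YAML and every stage draws its
randomness from a named substream of the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import numpy as np
import yaml


@dataclass
class RunConfig:
    """Pipeline configuration.

    Parameters
    ----------
    min_frames:
        Minimum number of frames a track must be detected in (track filter).
    max_gaps:
        Maximum number of single-frame gaps allowed per track.
    min_displacement_um:
        Minimum net displacement in micrometres a track must travel.
    min_persistence:
        Minimum persistence (net displacement / path length), exclusive.
    min_fraction_in_fov:
        Cells capturing less than this fraction of their body inside the
        field of view are excluded entirely.
    displacement_rule:
        ``"net"`` interprets the minimum-travel filter as net displacement;
        ``"path"`` as total path length.
    coherence_radius_um:
        Neighborhood radius for local track coherence.
    coherence_include_self:
        Whether a track's own direction participates in its coherence
        average.  The self-inclusive form maps parallel tracks to 1.0 and a
        symmetric radial arrangement to exactly 0.0.
    curvature_variant:
        ``"standard"`` plane-curve formula or ``"as_printed"`` legacy
        variant (see :func:`cometdyn.features.mean_curvature`).
    edge_norm_scope:
        Scope of the min-max scaling of the edge-distance feature:
        ``"cell"`` (default) or ``"dataset"``.
    circularity_bins / circularity_bin_labels:
        Half-open circularity bin edges and their labels.
    contact_scheme:
        ``"invitro"`` (contact <5 um, nearby [5, 30], far >30 um) or
        ``"invivo"`` (proximal <2 um vs distal).
    n_permutations:
        Cell-label permutations for the rank-sum permutation test.
    subsample_cells / max_tracks_per_cell:
        Equal-cells subsampling applied once before permutation testing;
        ``None`` disables.
    bh_q:
        Benjamini-Hochberg false-discovery level for the per-feature family.
    seed:
        Master seed; all stage randomness derives from it.
    """

    # track filters
    min_frames: int = 3
    max_gaps: int = 1
    min_displacement_um: float = 0.5
    min_persistence: float = 0.60
    min_fraction_in_fov: float = 0.8
    displacement_rule: str = "net"

    # features
    coherence_radius_um: float = 20.0
    coherence_include_self: bool = True
    curvature_variant: str = "standard"
    edge_norm_scope: str = "cell"

    # shape / proximity
    circularity_bins: tuple = (0.0, 0.4, 0.7, 1.0)
    circularity_bin_labels: tuple = ("low", "medium", "high")
    contact_scheme: str = "invitro"

    # statistics
    n_permutations: int = 1000
    subsample_cells: int | None = None
    max_tracks_per_cell: int | None = 25
    bh_q: float = 0.05
    kl_bins: int = 50

    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        for name in ("min_displacement_um", "coherence_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_persistence < 1:
            raise ValueError("min_persistence must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        edges = np.asarray(self.circularity_bins, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("circularity_bins must be strictly increasing edges")
        if len(self.circularity_bin_labels) != len(edges) - 1:
            raise ValueError("one label per circularity bin required")
        if self.displacement_rule not in ("net", "path"):
            raise ValueError("displacement_rule must be 'net' or 'path'")
        if self.curvature_variant not in ("standard", "as_printed"):
            raise ValueError("curvature_variant must be 'standard' or 'as_printed'")
        if self.edge_norm_scope not in ("cell", "dataset"):
            raise ValueError("edge_norm_scope must be 'cell' or 'dataset'")

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream for a pipeline stage, derived from the master seed.

        The substream is a deterministic hash of (seed, stage name), so adding
        a stage never perturbs the randomness of existing ones.
        """
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return np.random.default_rng(int.from_bytes(digest[:8], "little"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["circularity_bins"] = list(d["circularity_bins"])
        d["circularity_bin_labels"] = list(d["circularity_bin_labels"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("circularity_bins", "circularity_bin_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
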