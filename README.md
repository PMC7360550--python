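# cometdyn

Quantitative analysis of microtubule (MT) plus-end comet dynamics in cells,
together with the cell-shape, macrophage-proximity, migration and
ligand–receptor analyses that surround it in tumor-microenvironment imaging
studies.

## The problem

Growing microtubule plus-ends can be labeled with end-binding proteins
(EB1/EB3) and appear in fluorescence time-lapse movies as moving "comets".
Particle-tracking software turns those movies into track tables; the
scientific questions live one level up: are a cell's MTs growing coherently
in one direction or radiating isotropically? Are they aligned with the
cell's long axis? Do those phenotypes shift when tumor cells sit next to
M2-polarized macrophages, and is cell elongation spatially associated with
macrophage contact?

`cometdyn` implements that analysis layer as a tested library:

* **Strict track filters** — a track is kept only if it lies in a marked
  cell, was detected in ≥ 3 frames, has ≤ 1 gap, travels ≥ 0.5 µm, has
  persistence > 0.60, and its cell keeps ≥ 80 % of its body in view.
* **14 per-track features** — average/min/max/SD growth speed (µm s⁻¹),
  net displacement, path length, persistence = displacement/path,
  mean curvature κ of a cubic fit (κ = |x′y″ − y′x″| / (x′² + y′²)^{3/2}),
  normalized distances to the cell edge, major axis and minor axis,
  local (20 µm) and cellular directional coherence, and orientation
  cos θ to the cell's major axis.
* **Statistics** — per-feature variance-stabilizing transforms and PCA;
  a cell-label permutation test (Wilcoxon rank-sum statistic, whole cells
  shuffled between groups, p floored at 1/n_perm) with Benjamini–Hochberg
  correction; Cohen's D with two pooled-SD variants; histogram K–L
  divergence between PC1 distributions; clustergram matrices.
* **Shape & proximity** — circularity 4πA/P², eccentricity, solidity,
  convexity; circularity binning; distance-transform macrophage proximity
  with contact/nearby/far categories; chi-squared enrichment;
  Otsu-threshold overlap association; batch-mean group comparisons with
  Tukey-fence outlier exclusion.
* **Migration** and **ligand–receptor scoring** (mean ligand × mean
  receptor per cell-type pair, normalized to the maximum).
* A **synthetic-data subpackage** that generates every input with known
  ground truth — von Mises track directions about the cell axis
  (concentration `kappa_dir` dials coherence), elliptical cell masks with
  analytic circularity, rendered comet movies with controlled Gaussian
  noise, proximity fields with a planted elongation–contact association —
  plus a simplified difference-of-Gaussians detector and
  mutual-nearest-neighbor linker for benchmark movies.

Coherence is the average cosine between unit net-displacement directions
within a scope (including the query track), so a cell whose tracks all
move together scores 1.0 and a symmetric radial array scores exactly 0.0.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study
(outputs under `results/`):

```bash
python analysis/01_simulate_data.py
python analysis/02_track_features.py
python analysis/03_multivariate_stats.py
python analysis/04_shape_proximity.py
```

`01` generates two conditions that differ only in directional
concentration — a diffuse "monoculture" (`kappa_dir = 0.5`) and an aligned
"il4_coculture" (`kappa_dir = 3.0`) — plus a macrophage proximity field
with a planted association. `02` prints, for this seed:

```
condition means:
               cellular_coherence  orientation  speed_avg
il4_coculture               0.708        0.848      0.361
monoculture                 0.063        0.661      0.352
```

i.e. the filters and features recover the planted contrast: the aligned
condition has high cellular coherence and axis orientation while growth
speeds (~0.35 µm s⁻¹, the scale the generator emulates) are untouched.
`03` then reports which features the cell-label permutation test flags
after BH correction:

```
features significant after BH (q < 0.05): ['path_length', 'local_coherence',
                                           'cellular_coherence', 'orientation']
two-feature PC1: KL(il4_coculture||monoculture) = 2.077
```

and `04` recovers the planted shape–proximity association from the masks
alone:

```
30 cells; circularity error vs analytic ground truth: max 0.011
chi-squared = 18.04 (p = 0.0012); low-circularity contact/far ratio = 2.33
```

The same steps are available as a CLI (`cometdyn simulate | detect |
features | stats | shape | migrate | lrscore | run-all`) for use on real
track exports and masks.

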