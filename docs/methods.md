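# Methods

This note documents the models, conventions and numerical choices behind
`cometdyn`, in the order data flows through the pipeline.

## Coordinates, units, ingestion

Track files store one comet observation per row (`track_id, cell_id,
frame, x, y`), pixel-valued by default (an `um` flag accepts metric
exports). Coordinates are converted to micrometres once at ingestion using
the image pixel size; frames are 0-based with the image convention (origin
top-left, y down). All downstream code works in µm and seconds. Frames
must increase strictly within a track and a track belongs to exactly one
cell; violations are rejected at read time with the offending track named.

## Cell geometry

Per-cell geometry comes from the labeled mask: centroid and axis lengths
from `skimage.measure.regionprops`, the major-axis angle from the
eigenvectors of the pixel covariance (computed directly in the x/y
convention to avoid orientation-convention mistakes, folded to
(−π/2, π/2] since an axis is undirected), the interior distance transform
from `scipy.ndimage.distance_transform_edt` scaled to µm, and the boundary
from the longest marching-squares contour. `fraction_in_fov` is the
fraction of the cell's area inside the stated field-of-view box; cells
clipped by the image border report area-inside/area-total, which is
conservative for the ≥ 80 %-in-view exclusion.

## Track filters

Filters run in a fixed order and the first failing rule is charged in the
rejection report: (1) marked cell, (2) cell ≥ 80 % in view, (3) detected
in ≥ 3 frames, (4) at most one missing frame, (5) travel ≥ 0.5 µm,
(6) persistence > 0.60. "Travel" is net displacement by default; a config
flag switches to path length. Gap counting uses total missing frames, so a
two-frame gap fails rule 4 when the limit is one.

## The 14 features

* **Speeds** — per-frame velocities by central differences on the true
  acquisition times (one-sided at endpoints), so a bridged gap contributes
  a speed over the doubled interval rather than an inflated per-sample
  jump. The SD is the population SD of the per-frame speeds.
* **Displacement, path length, persistence** — |end − start|, summed step
  lengths, and their ratio in (0, 1]; a coincident start/end yields
  persistence 0 and the track is flagged (it cannot pass the filters).
* **Curvature** — cubic least-squares fits of x(t), y(t) (degree reduced
  to n−1 for short tracks), differentiated analytically; the plane-curve
  curvature |x′y″ − y′x″| / (x′² + y′²)^{3/2} is evaluated per frame and
  averaged. A legacy variant (`as_printed`) evaluating
  |x′(y′)² − y′(x′)²| / (x′² + y′²)^{3/2} is retained for comparison with
  earlier analyses; it is not a geometric curvature (it does not vanish on
  oblique straight lines) and is regression-locked in the tests rather
  than interpreted. Frames with near-zero speed are excluded from the
  average; all-stationary tracks are flagged undefined.
* **Edge distance** — mean distance-transform value along the track
  divided by the cell's mean interior distance (cell-size normalization),
  then min–max scaled to [0, 1] within each cell. Per-cell scaling was
  chosen because the normalization is cell-centric; a dataset-wide option
  exists. If a scope's raw values coincide the feature is set to 1.0
  (every track is simultaneously the maximum).
* **Axis distances** — perpendicular distance of the track centroid to
  the major (minor) axis line divided by the farthest boundary point from
  that axis, clamped to [0, 1]. The centroid was chosen as the track's
  reference point (symmetric and stable); per-point averaging would be the
  alternative.
* **Coherence** — a track's direction is its unit net-displacement
  vector. Local coherence averages the cosine between the query's
  direction and those of same-cell tracks whose centroids lie within
  20 µm; cellular coherence uses all of the cell's tracks. The query is
  included in its own average: only the self-inclusive form maps parallel
  tracks to exactly 1.0 and a symmetric radial array to exactly 0.0 at
  finite n (self-exclusion gives −1/(n−1)), and it makes the cell-level
  mean equal |mean direction vector|², an identity the tests assert to
  1e-12. A config flag restores self-exclusion.
* **Orientation** — cos of the acute angle between the track's net
  displacement and the cell's major axis; 1 parallel, 0 perpendicular,
  0.71 at the 45° boundary.

Tracks with any undefined feature are dropped at table assembly with a
count recorded on the table.

## Statistics

* **Transforms** — log for the right-skewed magnitudes (speeds, speed SD,
  displacement, path length, curvature), √x for the axis distances,
  √(1−x) for the left-skewed bounded features (orientation, persistence),
  identity otherwise; then z-scoring. Non-positive values under log raise
  rather than being silently offset.
* **Outlier removal** — percentile mode keeps rows inside the [5, 95]
  percentiles of every selected feature (bounds from the input, not
  iterated; pooled across conditions); the clustergram path uses the
  3-SD variant.
* **PCA** — `sklearn.decomposition.PCA` on the scaled matrix with a
  deterministic sign convention (each component's largest-|loading| entry
  positive). The two-feature PC restricts to orientation and cellular
  coherence, z-scored, and fixes the sign so higher orientation means
  higher PC1.
* **Permutation test** — the observed statistic is the two-sided Wilcoxon
  rank-sum p on track-level values; permutations reassign whole cells
  between the two groups preserving group cell counts, so within-cell
  correlation is respected. The reported p is the fraction of
  permutations with a strictly smaller p than the observed one, floored
  at 1/n_perm (1000 permutations → floor 0.001). Strict counting follows
  the procedure as stated and is mildly anti-conservative; a `le` option
  counts ties. Optional equal-cell and ≤ 25-tracks-per-cell subsampling is
  drawn once before testing, not per permutation. BH correction is applied
  across the feature family only, at Q = 0.05.
* **Cohen's D** — (µ₁ − µ₂)/SD_pooled. The default pooled SD is
  √(Var₁ + Var₂)/2 (the form used in the analyses this package follows);
  the `classic` variant √((Var₁ + Var₂)/2) differs by exactly √2, an
  identity the tests assert. Batch mode computes D per experimental run
  and averages.
* **K–L divergence** — fixed-bin histograms (default 50 bins spanning the
  pooled range) with one pseudo-count per bin before normalization;
  reported asymmetrically both ways plus the symmetrized mean. Histograms
  were chosen over density estimation for bit-exact reproducibility; the
  estimator recovers the Gaussian closed form Δµ²/2 within 15 % at n = 10⁵.
* **Group comparisons** (shape/migration) — per-batch means, Tukey-fence
  (1.5 IQR) exclusion among batch means, then a two-sided t or
  Mann–Whitney test on the surviving means. The fence step is mildly
  anti-conservative when batches are few; the null test in the suite uses
  eight batches per group.

## Shape and proximity

Circularity is 4πA/P² with the perimeter measured on the largest
marching-squares contour after closed-curve Gaussian smoothing (σ = 2
contour samples, wrapped). The raw staircase contour overestimates smooth
perimeters by ~5 % (pushing a rasterized disk's circularity to ~0.90) and
the Crofton estimate underestimates axis-aligned polygons by ~6 %; the
smoothed contour hits both anchors (disk 0.998; 4:1 ellipse 0.539 vs the
elliptic-integral value 0.536; 4:1 rectangle 0.528 vs 0.503). Convexity,
which lacks a universal definition, is convex-hull perimeter ÷ perimeter.
Circularity above 1 by up to 0.05 (rasterization) is capped with a flag.

Macrophage proximity is the minimum, over a tumor cell's pixels, of the
distance transform of the macrophage mask's complement. Contact categories:
in-vitro contact < 5 µm, nearby up to 30 µm, far beyond (the printed
5–6 µm seam maps [5, 6) to nearby); in-vivo proximal < 2 µm. Enrichment is
Pearson chi-squared without continuity correction on the bin × category
table, with per-bin contact/far ratios. The published in-vivo bin preset
assigns "high" to [0.7, 0.8) and "medium" to [0.8, 1.0) — an apparent
label swap that the preset reproduces verbatim; labels are configurable.

## Detection and linking

The detector is a deliberately simple front end for synthetic benchmark
movies, not a re-implementation of multi-hypothesis trackers: a
difference-of-Gaussians band-pass (low-pass σ 1–3 px, high-pass σ 4–5 px),
a threshold of 2–3 robust SDs (1.4826 × MAD) above the background median,
3×3 intensity-weighted centroid refinement, then mutual-nearest-neighbor
linking with a distance gate and at most one bridged frame (at doubled
gate). Mutual nearest neighbors make failures conservative — fragmentation
rather than identity switches — which is the right failure mode for
validating features downstream.

## Synthetic data: what it emulates and what it does not

The generators emulate the statistical structure the analysis assumes:
track directions follow a von Mises law about the host cell's major-axis
angle with concentration `kappa_dir` (exactly uniform at 0, so coherence
is a monotone function of one knob); speeds are per-track Gaussian draws
around 0.35 µm s⁻¹ (SD 0.15, the in-vitro scale), frame intervals default
to 1 s (within the 0.8–2.7 s acquisition range), tracks run 5–12 frames
with a 10 % chance of one interior gap and 0.05 µm per-point positional
noise. Masks are rasterized ellipses (default 0.25 µm/pixel, typical 60×
confocal sampling) with analytic area/perimeter ground truth. The
proximity generator seeds a fixed fraction (0.4) of tumor cells touching a
macrophage independent of shape, then draws elongation with a log-odds
shift of `association_strength` for contact cells over a base elongation
probability of 0.2; elongated cells use axis ratios 5–8 so they fall in
the low-circularity bin, round cells 1–1.3. At strength 0 shape and
proximity are independent by construction, which is what makes the
chi-squared null calibration test meaningful. Migration series are
persistent random walks at 0.15 µm min⁻¹ sampled every 10 min; expression
matrices are gamma-Poisson counts with cell-type-specific means.

Passing tests on these fixtures shows the *computations* are correct and
the planted effects recoverable; it does not validate segmentation
quality, tracking under dense comet fields, photobleaching, 3-D effects,
or any biological claim — real data enters through the same CSV/TIFF
readers and inherits whatever upstream errors its masks and tracks carry.

## Problem sizes

Simulation-backed tests are sized to establish each property with
comfortable margins at desk scale: the permutation type-I check uses 200
null datasets of 12 cells × 15 tracks at 200 permutations; coherence
recovery uses 2 cells × 100 tracks per concentration; the planted
proximity association was verified over 100 generator seeds during
design (96/100 recovered at strength 3.5, 2 % null rejection at
strength 0). The analysis drivers use 8 cells × 40 tracks per condition
and 1000 permutations.

## Known limitations

Everything is 2-D; shrinkage/pause/catastrophe statistics are out of scope
(plus-end labels mark growth only). The permutation p's strict-inequality
counting and floor make it slightly anti-conservative near the floor. The
legacy curvature and pooled-SD variants are preserved for comparability,
not endorsed. Chi-squared enrichment on small fields can have sparse
cells; the implementation raises on zero expected counts rather than
merging bins silently.
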