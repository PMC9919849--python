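# Methods

`railphen` re-implements, as a tested library, the data path of a rail-borne
LiDAR phenotyping platform for potted crops: a 16-beam 360° scanner rides an
electric slide rail under a ground vehicle, the vehicle stops every 1.90 m
along a crop row, and each stop's frame stream is turned into a dense block
cloud, merged into a strip, and reduced to two traits per plant — height and
maximum crown width.  This note documents the model behind each stage, the
parameters that matter, what the synthetic scenes do and do not emulate, and
the numerical choices made where the design was open.

## Coordinate conventions

All lengths are meters.  Two frames appear:

* **Raw sensor / block frame** — what frames, stitched blocks, and the merged
  strip are in.  The rail travel axis is +z; the scanner's spin axis lies
  along the rail, so the beam fan (±15° in 2° steps) spans *along* the travel
  axis and the 360° azimuth sweep circles under the sensor.  The true
  vertical is approximately sensor +y (the sensor sits `mount_height` = 1 m
  above the ground).
* **Calibrated frame** — after horizontal calibration the fitted ground
  normal is exactly +z, and plant heights are read off the z axis.

## Frame stitching

The rail moves at constant speed `a` (stock setting 344 cm/min ≈ 0.0573 m/s)
while the scanner records `f` = 15 frames/s, so frame `k` was taken with the
sensor displaced `k·a/f` along the travel axis.  Stitching translates every
point of frame `k` by that displacement (`P′ = P + d_k`) and superposes the
frames.  Frames are treated as instantaneous snapshots; motion distortion
within one 360° sweep (≈ 3.8 mm of travel at stock settings) is not modeled.
Config accepts the platform's mixed units (mm/s, cm/min) and converts to
m/s at parse time.

## Block registration

Blocks are spaced a known 1.90 m, so block `k` is coarse-aligned by a
`(k−1)·1.90 m` translation, then refined with point-to-point ICP: nearest-
neighbor correspondences for every target point (gated at `max_corr_dist`,
default 5 cm), closed-form rigid least-squares update (centroid subtraction,
cross-covariance SVD, reflection guard), iterate until the mean
correspondence distance `d` drops below `d_threshold`, stops changing
(|Δd| < 1 mm/1000), or the iteration cap is hit.

Implementation choices that matter in practice, all switchable:

* **Odometry-style initialization.** The strip is anchored in block 1's
  frame, so any tilt of block 1 displaces distant strip content by
  ≈ 26 mm per meter per degree.  Starting block `k` from the previous
  block's *refined* pose plus the incremental 1.90 m offset keeps the
  initial misalignment bounded by the relative stop error, independent of
  strip length.
* **Trimmed estimation.** The least-squares update uses only pairs within
  3× the median pair distance (floor 5 mm).  Untrimmed, pairs at the overlap
  boundary (strip content the new block never saw) bias the update by
  centimeters.  `d` itself is still evaluated over the full gated pair set,
  so the convergence test is not distorted by the trimming.
* **Best-iterate tracking.** If `d` rises to twice the best value seen, the
  best iterate is returned instead of the last — plain ICP can walk away
  from a good pose when the trimmed subset degenerates.
* **Plausibility guard.** A refinement moving the block more than 20 cm or
  10° is rejected — a rail stop cannot really be that far off — and the
  prior placement is kept (with a warning).  This replaces "fall back on
  non-convergence": with 2 mm range noise the mean pair distance has a noise
  floor, so a literal `d < 1 mm` convergence test would reject essentially
  every real alignment.

For dense strip runs the analysis configuration (`PipelineConfig.for_strip`)
sets `d_threshold` to 0.1 mm so ICP runs to geometric stall; the duplicate
returns of a slow rail scan (each surface patch is swept by many frames)
push nearest-neighbor distances well below the noise level, which makes a
1 mm mean-distance test fire several iterations too early.

## Noise removal and ground detection

Statistical outlier removal scores each point by its mean distance to its
`k` nearest neighbors (default k = 20) and removes points above
`μ + α·σ` of that score distribution.  The cutoff is one-sided: an unusually
small neighbor distance never indicates a sparse outlier.

The ground is fitted by seeded RANSAC: sample 3 points, build the exact
plane through them (the cross-product coefficient form), count points within
the distance threshold ΔT1 (default 1 cm), keep the max-inlier model
(first winner on ties), 1000 iterations by default.  The winning minimal-
sample model is then polished by a least-squares plane fit (SVD) on its
inliers and the mask recomputed; set `refit=False` for the raw 3-point
model.  Planes are stored normalized (‖(A,B,C)‖ = 1) and canonicalized to
C ≥ 0 (then B, then A on ties).

Horizontal calibration rotates the fitted normal onto (0,0,1) about their
cross product (Rodrigues).  Because the raw-frame ground normal is nearly
horizontal (≈ +y), the C ≥ 0 canonicalization cannot decide which side is
"up"; the pipeline therefore orients the normal toward the off-plane (crop)
points before calibrating.  An exactly antipodal normal is handled by a
conventional 180° rotation about x.  Ground inliers are removed after
calibration, before clustering.

## Single-plant segmentation

Euclidean clustering groups points within distance `r` (default 5 cm) of
each other — implemented as exact connected components of the
r-neighborhood graph (KD-tree pair enumeration + union over components),
which is what KD-tree region growing computes.  Clusters below
`min_cluster_size` (default 100) are discarded as noise and counted.

Where plants interlock, the merged component is split by seeded Lloyd
K-means (k-means++ initialization, termination when the assignment stops
changing).  Merged components are detected automatically: given an expected
plant count, the largest clusters are flagged with
`K = round(size / median size)` until the counts reconcile; without an
expected count, any cluster exceeding 1.8× the median size is flagged.  The
original procedure identified the four merged plants by eye and chose K = 4
manually; the size rule automates exactly that judgement and reproduces the
K = 4 case.  Final clusters are labeled `plant_001…` in ascending
travel-axis order of their centroids (across-row coordinate as tie-break).

## Trait extraction

* **Height** `h = Z_max − Z_min − h_p`: literal maximum z of the cluster,
  minus the ground-plane elevation evaluated at the cluster's xy centroid
  (robust to residual tilt; the global plane minimum would leak tilt into
  every height), minus the known pot height `h_p` (default 0.10 m).
  Non-positive heights are flagged invalid, not clamped.  The only guard on
  `Z_max` is the upstream outlier filter; a percentile option exists in the
  code but defaults off.
* **Maximum crown width** `L`: points at or below the pot rim
  (z ≤ Z_min + h_p) are dropped so a wide pot cannot define the crown; the
  rest is projected to xy, hulled (monotone chain, CCW, collinear edge
  points dropped), and the farthest antipodal vertex pair found by Shamos'
  rotating calipers — a single linear sweep of two parallel supporting
  lines.  Distances are compared squared, so the result is bit-identical to
  the brute-force farthest pair.
* **Agreement**: ordinary least squares of estimated on measured gives
  slope/intercept/R²; RMSE is computed on raw paired differences, not
  regression residuals.  Manual "maximum crown width" is interpreted as the
  hull diameter (the measurement protocol is not recorded more precisely).

## Synthetic scenes and scanner emulation

The simulator provides ground truth the real study cannot (its scans are
not deposited): parametric potted-plant strips with per-point labels, known
stop-pose errors, and truth recomputed *from the realized surface samples*,
so recovery error measures the pipeline, not sampling chance.

Scene model: a ground plane with configurable tilt (default 0.5°) and
Gaussian roughness (σ_g = 3 mm), sampled on a 6 cm quasi-grid whose sample
positions are jittered within each cell — a perfect lattice would hand ICP
spurious cell-shifted optima that real quasi-continuous ground returns do
not have.  Each plant is a pot cylinder (wall band, rim ring, soil disk), a
stem, and a rosette of ellipsoidal leaf clusters sampled in their volumes
(a multi-echo scanner sees canopy interiors), with petiole chains keeping
the rosette connected at realistic clustering radii.  Samples per leaf are
allocated proportional to leaf volume and plant size so density is roughly
uniform.  Realized samples are rescaled so each plant hits its drawn target
height and crown width exactly; truth is then recomputed from the samples
(brute-force farthest xy pair; max canopy z minus local ground minus pot
height).  Defaults describe the emulated study: 9 stops × 6 plants = 54
potted lettuce in two rows 0.5 m apart, pots every 0.6 m, heights
0.10–0.35 m, crowns 0.15–0.40 m, pot height 0.10 m.

Scanner emulation: 16 beams at ±15°/2° steps with an effective beam
footprint half-width of 0.15° (multi-beam units have ≈ 0.1–0.2° beam
divergence), azimuth binned at 0.2° with one return — the nearest — per
(beam, azimuth bin) per frame, maximum range 10 m, 15 frames/s, 1 m mount
height.  Rail travel per stop is sized so block extents overlap 30 % at the
1.90 m stop spacing.  Gaussian range noise (default σ = 2 mm) is applied
along the line of sight.  Stop-pose errors are random rigid motions (up to
2° / 3 cm by default) applied per block and recorded as truth.

Not emulated: occlusion ray-casting (deliberate — multi-echo penetration
makes canopy interiors sampleable, and the omission keeps the noise-free
round trip exact), radiometric intensity, beam divergence ellipses, motion
distortion within a frame.  Consequences for interpretation: passing tests
show the *pipeline* recovers what the scanner geometry could see; they do
not certify performance under heavy self-occlusion or leaf movement.

A real-data caveat worth naming: because every surface patch is swept by
~10–20 frames, the stitched cloud contains near-duplicate returns, and the
height estimator's literal maximum rides on the upper tail of the range
noise (≈ +3–4 mm bias at σ = 2 mm).  The real platform shows the same
redundancy (hundreds of thousands of points per plant).

## Analysis configuration for strip runs

`PipelineConfig.for_strip` differs from the bare operation defaults in two
places, both consequences of the duplicate-heavy return pattern:

* SOR uses k = 12, α = 2.5 (instead of 20 / 1.0).  Points near plant tops
  are swept by about half as many frames as ground points (they are closer
  to the spin axis), so with k = 20 their k-neighborhoods reach past their
  own duplicates and a 1σ cutoff amputates the very maxima Eq-style height
  extraction depends on.  With k = 12 and a 2.5σ cutoff the filter removes
  isolated error points and little else.
* ICP runs to stall (`d_threshold` 0.1 mm, 60 iterations) as explained
  above.

With zero range noise the filter has nothing to remove and is set
effectively off (α = 6).

## Problem sizes and determinism

The shipped experiments use the 54-plant strip (~0.5 M raw returns,
~350 k after ground removal), which runs end to end in about a minute on a
single core; unit and property tests use 2-stop strips of 6–12 plants.
Every random draw — scene, scan noise, stop perturbations, RANSAC, K-means —
derives from explicit integer seeds via independent `SeedSequence` streams,
so identical configs produce byte-identical trait tables.

## Known limitations

* Sequential pairwise registration accumulates link error along the strip;
  there is no global (pose-graph) relaxation.  With the odometry prior the
  drift is sub-millimeter per link under study conditions, but pathological
  overlaps (featureless ground at a strip end) are handled only by the
  plausibility guard.
* `detect_merged` assumes roughly comparable per-plant point counts; plants
  differing in size by more than ~2× would confuse the size-ratio rule.
* Heights below the pot rim are invisible (flagged invalid), and the
  literal-maximum height rule inherits the range-noise upper tail.
* The evaluation pairing helper assumes pot centers are farther apart than
  the residual registration error (true by a wide margin here).
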