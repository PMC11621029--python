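# Methods

This document defines the quantities `bflow` computes, the defaults it
ships with, and the boundaries of its synthetic-data validation. Units are
given in brackets.

## 1. Tracking input and cleaning

A recording is a set of named body-point tracks `(x, y, likelihood)` per
frame, at a fixed frame rate (`fps`, default **25 frames/s**). Two CSV
dialects are supported: the three-header-row "scorer/bodyparts/coords"
layout and a flat `point_x, point_y, point_likelihood` layout (missing
likelihood columns default to 1.0).

**Arena calibration.** Four tracked corner points define the arena
polygon; each vertex is the per-coordinate median of its track. The pixel
scale is `px_per_cm = sqrt(area_px / real_size_cm²)`. Default zones are a
concentric center (linear scale **0.5**) and the remaining periphery;
zones are tested in declaration order, so nested definitions behave as a
partition and per-zone times sum exactly to the recording duration.

**Cleaning.** A sample is masked when its likelihood is below the
threshold (default **0.95**) or it falls outside the *existence polygon*
(the arena scaled by **1.3** about its centroid). Masked samples are
refilled by linear interpolation in time; edge gaps take the nearest valid
value. Speed [cm/s] is the first difference of position times `fps`;
acceleration [cm/s²] is the first difference of speed times `fps`, both
padded by replication to keep the frame count.

## 2. Features and temporal expansion

The default registry holds **41 features** of five kinds:

| kind | count | value | normalization |
|---|---|---|---|
| point_acceleration | 13 | point acceleration [cm/s²] | linear × 4 |
| pair_distance | 12 | inter-point distance [cm] | per-recording z-score |
| pairpair_angle | 6 | signed angle between two segments, (−π, π] [rad] | none |
| border_proximity | 6 | distance to arena border [cm] | linear × 0.1 |
| polygon_area | 4 | shoelace area of a point polygon [cm²] | per-recording z-score |

Z-scoring is per recording; zero-variance distance/area features map to 0
with a warning. **Temporal expansion** concatenates each frame's feature
vector with its neighbors at offsets −15 … +15 (halfwidth **15**, window
length **31**), giving 41 × 31 = **1,271** columns, offset-major
(`name@-15 … name@+15`). Frames whose window is incomplete are dropped;
the surviving rows carry a `frame_offset` so downstream labels stay
aligned with the original frames.

## 3. Clustering

Training rows are pooled from an equal-sized random sample of recordings
per experiment (sorted experiment order, seeded sampling without
replacement). Columns are z-scored with statistics persisted in the model
(zero-variance columns map to 0 and are kept so the layout is stable);
k-means (scikit-learn, `n_init` default **3**, seeded) runs in the
standardized space, and prediction assigns the nearest center (ties to the
lowest cluster id). The default cluster count is **25**. When choosing a
count from observed cluster usage, `select_cluster_count` returns the
smallest number of clusters whose (descending) usage proportions cover
**95 %** of frames.

## 4. Cluster stabilization

To compare experiments clustered at different times, a supervised
classifier is trained to imitate the reference clustering and is then
applied to new recordings ("classifier-in-the-middle"). Two
implementations are provided:

- `ClusterImitationClassifier` — a NumPy multilayer perceptron with one
  hidden layer of **1,024** ReLU units, inverted dropout **0.4**, softmax
  output, cross-entropy loss, RMSProp (learning rate **10⁻³**, decay
  **0.9**, epsilon **10⁻⁷**), **30** epochs, batch size **512**, Glorot
  uniform initialization, fully seeded.
- `LogisticClusterClassifier` — multinomial logistic regression; the
  lightweight default for cross-validation at desk scale.

Transfer quality is assessed by **recording-level k-fold cross-validation**
(default **10** folds): recordings, never frames, are shuffled and
partitioned, so no frame of a validation recording is seen in training.
Per-cluster precision, recall, and F1 are computed on the pooled held-out
frames of each fold.

## 5. Behavioral flow

**Smoothing.** Each frame's label is replaced by the modal label in a
±`halfwidth` window (default **5** frames; windows shrink at the edges;
ties break to the smallest cluster id).

**Transition matrix.** Consecutive repeats are collapsed into runs (the
"occurrence vector"); cell `(j, k)` counts how often a run of `j` is
immediately followed by a run of `k`. The diagonal is structurally zero
and `Σ cells = runs − 1` exactly. With 25 clusters the matrix has 625
cells; 70 clusters give 4,830 possible ordered off-diagonal transitions.

**Stabilized matrix.** `S_i = T_i − mean(T_controls)` (elementwise). The
mean of the controls' stabilized matrices is exactly zero.

## 6. Group statistics

**BFA permutation test.** Observed statistic
`D = Σ_jk |mean_C(T)_jk − mean_T(T)_jk|`. Group assignments are permuted
`N` times (default **1,000**) preserving group sizes; the null is the
vector of permuted distances `D_b`. Reported:

- `percentile = 100 · #{D_b < D} / (N + 1)` (strict inequality; ceiling
  `100 · 1000/1001 ≈ 99.9`),
- `z = (D − mean(D_b)) / sd(D_b)`,
- `P = (1 − erf(z/√2)) / 2`, evaluated as `0.5 · erfc(z/√2)` so relative
  precision survives for large `z`. Worked checks: `z = 3.09 → P ≈
  1.01×10⁻³`; `z = 5.72 → P ≈ 5.3×10⁻⁹`.

The permutation loop is vectorized: with the signed weight vector
`w = (+1/N_C …, −1/N_T …)`, every permuted distance is a row of
`|W @ X|·1` for the stacked flattened matrices `X`.

**Per-transition tests.** The tested family is the *observed* transitions
(cells with a nonzero total count across both groups, diagonal excluded).
Welch's t-test per cell (pooled-variance optional), corrected by
Benjamini–Yekutieli FDR.

**BFL score.** For sample `i`, `M_A` and `M_B` are the elementwise median
matrices of groups A and B, each computed leave-one-out when `i` belongs
to that group. With Manhattan distances `d_A = d(T_i, M_A)`,
`d_B = d(T_i, M_B)`: `BFL_i = log(d_A / d_B)`. A zero distance gives an
infinite score flagged as degenerate. Group separation is summarized by
absolute Cohen's d with `(n−1)`-weighted pooled SD (infinite scores
excluded with a warning). **Responders** are treated animals whose score
falls outside the closed range of control scores.

**Power and sensitivity.** Power curves use the noncentral-t two-sample
power (two-sided, default α = 0.05) on a per-group size grid of
(3, 4, 5, 6, 7, 12, 20, 30, 50, 60); `power(d = 0) = α` exactly. The
sensitivity assay redraws equally sized subgroups (default sizes 25, 20,
15, 10, 5; **50** repetitions) and summarizes `−log₁₀ P` per size.

**Dose model.** OLS of `log(count)` on `log(dose)`; zero or negative
values are excluded (count reported); `R² = F/(F + df₂)` for this
single-predictor model. P values across several tested transitions can be
BY-adjusted.

## 7. Fingerprinting (BFF)

Per-animal transition matrices (raw counts or stabilized values) are
flattened row-major and embedded with UMAP (`n_neighbors` **15**,
`min_dist` **0.1**, seed **42**). Group summaries report mean ± s.e.m.
per embedding dimension. The UMAP import is deferred because its first
call triggers a ~30 s numba compilation.

## 8. Synthetic data

The generator emulates the *statistical* structure the pipeline consumes,
not animal biomechanics:

- `BehaviorKernel` — a zero-diagonal Markov transition matrix over
  behavioral states plus a geometric dwell-time distribution (default mean
  run **20** frames). Constructors: `uniform`, `random`, `cycle`.
- `GroupEffectSpec` — multiplies selected transition rates and
  renormalizes the affected rows (a multiplicative "flow" effect).
- Per-animal individuality — each animal's kernel is a Dirichlet
  perturbation of its group kernel (concentration default **200**;
  infinity reproduces the base kernel exactly).
- `simulate_pose` — renders a label sequence into a 13-point tracking
  table: a state-driven correlated random walk of the centroid (state
  styles set speed range [cm/s], heading noise [rad/frame], and
  longitudinal/lateral body-template scaling), reflection at a 15 %
  margin box, Gaussian landmark jitter (default **0.5 px**), independent
  likelihood dips (rate **0.02**), and four jittered static corner points
  for arena inference.

**Not emulated:** grooming-like oscillatory kinematics, occlusions with
correlated likelihood drops, camera distortion, non-square arenas in the
pose renderer, and inter-animal interactions.

## 9. Numerical and design choices

- Percentiles are on a 0–100 scale; the strict-inequality, `(N+1)`
  denominator convention makes 99.9 the exact ceiling for 1,000 shuffles.
- `erfc` rather than `1 − erf` for tail P values (see §6).
- Matrix distances and permutation nulls are exact floating-point sums in
  a fixed order; results are bitwise reproducible for a given seed.
- All stochastic components (sampling, k-means, classifier training,
  permutations, generators, UMAP) take explicit seeds.
- Estimators with fit/predict shape (`BehaviorKMeans`,
  `ClusterImitationClassifier`, `LogisticClusterClassifier`,
  `FlowEmbedding`) follow scikit-learn conventions (constructor-only
  hyperparameters, trailing-underscore fitted attributes, `get_params`).
- The test suite and acceptance script run at desk scale — group sizes of
  6–15 animals, 3–25 states, recordings of 10³–1.5×10⁴ frames — chosen so
  the full suite completes in minutes on one CPU while every structural
  identity (feature counts, window widths, matrix dimensions) matches the
  full-scale defaults.

## 10. Limitations

- The BFA P value is a normal-tail approximation of the permutation null;
  for very small groups the empirical percentile is the more faithful
  number (both are reported).
- BFL scores are undefined (infinite) when a sample coincides with a
  median matrix; such samples are flagged rather than silently dropped.
- k-means with few restarts can land in local optima when cluster shapes
  are far from isotropic; raise `n_init` for small-k problems.
- Per-recording z-scoring couples feature scales to each animal's own
  behavioral repertoire; strong occupancy shifts between groups can move
  cluster boundaries across recordings. This is inherent to the method,
  not an implementation artifact.
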