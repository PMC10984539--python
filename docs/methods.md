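# Methods

## The analysis model

The pipeline treats each imaging modality as a measurement of the same
latent representational geometry. For a set of stimulus conditions, a
representational dissimilarity matrix (RDM) is estimated per measurement
unit: per time point in MEG (pairwise decoding accuracy of sensor patterns)
and per voxel in fMRI (1 − Pearson correlation of t-value patterns inside a
searchlight sphere). Fusion asks, for every (location, time) pair, how
similar the two geometries are — Spearman correlation of the condensed RDM
vectors — while controlling a nuisance geometry (GIST image features) by
partial correlation. A stimulus-set contrast (High vs Low memorable, matched
in pairs) turns this into a localization problem: where and when does the
High-set fusion exceed the Low-set fusion?

Statistical decisions use two nonparametric devices. Over space × time, a
right-tailed sign-flip permutation test on the maximum cluster size controls
the family-wise error of the 4-D difference map; over time within an ROI,
onset latency is estimated by jackknife: leave-one-subject-out average
series are scanned for the first time point whose value, and each of the 10
consecutive non-overlapping 50 ms window means that follow it, reach 2× the
standard deviation of the grand-average baseline (−200..0 ms,
endpoint-exclusive). Because the n leave-one-out subsamples are almost
identical, the standard error of their onsets is inflated by (n − 1) —
equivalently the variance by (n − 1)² — before confidence intervals
(±t_crit · SE, t_crit = 2.145 at df 14) and t tests are formed.

## Estimator details and numerical choices

- **Partial Spearman** is rank-then-residualize: average ranks for ties,
  ordinary least squares with intercept to remove the confound ranks from
  both vectors, Pearson correlation of residuals. In the three-variable case
  this equals the closed form on ranks, which the vectorized fusion paths
  use; equality is asserted in tests. Missing RDM entries are handled
  pairwise-complete with at least 4 and at least 50% of pairs required,
  otherwise the cell is missing. A vector constant after ranking (or a
  target collinear with the confound, denominator ≤ 1e−12) yields NaN, never
  a fabricated value.
- **Decoding** bins the N single trials of each condition into
  floor(N / bin_size) pseudo-trials (bin size 3; leftovers are re-randomized
  every one of the `n_iterations` repetitions), trains a linear SVM (C = 1)
  on M − 1 pseudo-trials per class, and rotates the held-out pseudo-trial
  over all M folds. Features are used unscaled by default: the synthetic
  sensors are homoscedastic, and with M = 2 a per-feature z-score computed
  from one training sample per class degenerates to ±constant and destroys
  the pattern geometry; `standardize=True` restores training-set z-scoring
  for heterogeneous real data. With M = 2 the C-SVM decision boundary is
  analytically the perpendicular bisector of the two training points (any
  C > 0), so this case runs as a vectorized nearest-centroid rule; tests
  assert bit-equality with the sklearn SVM path. Bin assignments are keyed
  by (seed, iteration, condition id), which makes decoding a condition
  subset reproduce the corresponding sub-block of the full RDM exactly.
- **Searchlight** spheres are all integer offsets with ‖·‖ ≤ radius
  (257 voxels at radius 4), clipped to the brain mask; centers whose clipped
  sphere holds fewer than `min_voxels` (default 10) voxels are missing, and
  zero-variance condition patterns mark their pairs missing with a logged
  count. Voxel iteration order cannot affect results.
- **Cluster statistics** threshold the subject-mean map at the empirical
  (1 − p) quantile of its pooled in-mask baseline values (sort-based order
  statistic, no interpolation; per-voxel baselines are available via
  config). Connected components combine 26-neighborhood spatial adjacency
  (6/18 selectable) with ±1-sample temporal adjacency at the same voxel.
  Sign flips negate whole subject maps; cluster p-values use the
  (1 + #{null ≥ obs}) / (1 + n_perm) correction, so the smallest attainable
  p is 1/(n_perm + 1). A sign-flip test with S subjects has only 2^S flip
  patterns; below ~10 subjects it cannot resolve p < 0.01, which is why the
  calibration studies use 12 synthetic subjects.
- **Onset criterion 2** is read as: each of the 10 consecutive 50 ms windows
  starting at t individually has mean ≥ 2σ_b. The looser reading (one grand
  mean over the whole 500 ms span) is available as
  `OnsetConfig(criterion2="grand_mean")`. Onsets are searched from 0 ms; the
  stimulus-onset sample belongs to the post-stimulus period, and candidate
  times must be fully covered by the 500 ms criterion span. A zero baseline
  SD is an explicit error. A series is "not significant" unless *every*
  jackknife subsample has at least one significant time point.
- **Holm correction** delegates to
  `statsmodels.stats.multitest.multipletests(method="holm")`; tests re-check
  the step-down against a hand computation and the
  never-fewer-than-Bonferroni property.

## The synthetic-data generator

`SimConfig` defaults mirror the real design: 15 subjects, 78 High/Low pairs
(156 conditions), 25 trials/condition, −200..+1000 ms at 1 kHz (1201
samples), 306 sensors, memorability scores drawn at High 0.854 ± 0.089 and
Low 0.519 ± 0.105 (clipped to [0, 1]). `SimConfig.scaled()` is the
desk-scale test profile: 5 subjects, 10 pairs, 8 trials, 10 ms step
(121 samples), 16 sensors, 12³ grid. These problem sizes are the package's
standing evaluation conditions; the recovery and calibration studies in
`memfusion.benchmarks` use them unchanged.

Three mutually independent latent components generate all structure, each a
set of unit-norm k-dimensional feature vectors whose 1 − Pearson matrix *is*
the planted RDM: a **base** geometry (all conditions; expressed in MEG
within 100–1000 ms and in the fMRI t-maps of planted ROIs), a **divergence**
geometry (expressed in fMRI throughout but in MEG only by High conditions
from `onset_true` on — this is the planted effect, default amplitude 5× the
noise SD), and a **confound** geometry (both modalities and the
`confound_features` output, weight configurable per set). Latent vectors are
row-centered so the planted Pearson RDM coincides with the cosine geometry
that linear sensor/voxel projections actually realize.

Two design choices matter and were made deliberately:

1. **Pair-matched planting.** Latent vectors and fMRI voxel loadings are
   drawn per pair and assigned identically to both pair members, emulating
   the matched-pair design of the stimulus set. High and Low fusion series
   are then exchangeable before `onset_true` and differ afterwards only
   through the MEG expression of the divergence component. Without this, the
   two sets' sub-RDMs differ by a seed-dependent constant at small pair
   counts, which swamps a planted onset.
2. **Arc geometry.** Latent vectors sit on a great-circle arc between two
   random orthonormal axes at equally spaced, randomly permuted angles
   (default extent 1.5 rad). Isotropic random geometries at 10 pairs either
   saturate pairwise decoding at 100% — flattening the decoding RDM — or
   produce seed-dependent, unidentifiable rank structure. The arc keeps
   accuracies graded (~55–95%) and the planted ranks identifiable; an
   isotropic "cloud" style remains available.

What the generator does *not* emulate: temporally autocorrelated sensor
noise (noise is i.i.d. white per trial/sensor/sample), sensor covariance,
hemodynamic convolution or GLM estimation (t-maps are drawn directly as
signal + i.i.d. voxel noise), eye/muscle artifacts, inter-subject anatomical
variability (voxel loadings are shared across subjects; only noise is
subject-specific), and ramped or oscillatory response shapes (components
switch on as steps). Passing tests therefore demonstrate the *machinery* —
estimator correctness, calibration of the statistics, recoverability of
planted structure — not robustness to physiological noise structure.

Realistic single-trial MEG noise levels for this paradigm are not publicly
characterized; `noise_sd` defaults to 1.0 with all amplitudes expressed in
noise-SD units, and is configurable.

## Known limitations

- With a radius-4 searchlight on a 12³ grid, every ROI lies within one
  searchlight of the planted box, so neighbouring ROIs inherit a diluted
  copy of the effect; because fusion is rank-based, dilution barely lowers
  the correlation. Spatial specificity is bounded by the searchlight radius
  (the end-to-end tests use radius 2 where an uncontaminated control ROI is
  needed).
- The baseline noise of a fusion series scales as ~1/√(n_pairs_condensed)
  and, because the subject-averaged MEG RDM is shared, does not average out
  across subjects; at 10 pairs (45-dimensional RDM vectors) onset detection
  needs difference effects near the reliability ceiling. This is a property
  of the estimator at small condition counts, not of the implementation.
- Whole-map sign flipping makes very strong localized effects *harder* to
  certify (flipped means retain the blob for unbalanced flip draws); the
  planted-effect studies therefore use moderate effect-to-noise ratios.
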