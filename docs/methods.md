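# Methods

## Problem and data model

The package predicts a continuous behavioral (language) score from a binary
3D lesion mask on a fixed 61 × 73 × 61 grid at 3 mm isotropic resolution (a
standard down-sampled common brain space). Axis 0 runs left–right with the
left hemisphere at lower indices; vectorization of a volume is always C
order (last axis fastest), giving 271,633-entry feature vectors. Negative
scores denote deficit.

## Synthetic cohorts

Real cohorts of lesion masks with behavioral scores are clinical data and
cannot ship with the package, so every analysis runs on synthetic cohorts
with a known ground truth.

**Lesion shapes.** A lesion of volume V grows from a seed centroid by
random-walk dilation over the 26-neighborhood: at each step a random batch
(~35% of the current frontier) of boundary voxels is absorbed until exactly
V voxels are reached. This produces compact, irregular, single-connected
blobs; volumes are drawn log-uniformly from 5–5000 voxels, reflecting the
heavy-tailed spread of real stroke lesion volumes.

**Eloquent map.** The "ground-truth" lesion–behavior mapping is a weight
volume: a Gaussian bump (σ = 3 voxels) in the left perisylvian region
carrying 90% of the mass, plus a mirrored right-hemisphere bump with 10%
(language lateralization; right-hemisphere deficits are rare but possible).
Weights sum to 1.

**Scores.** score = baseline − effect_size × overlap + N(0, noise_sd), where
overlap is the map mass covered by the lesion. Defaults: baseline 2.0,
effect_size 15, noise_sd 1.9. The positive baseline reflects that empirical
battery scores are not centred on the no-lesion performance: with a
symmetric noise term and baseline 0, half of all unaffected patients would
fall below zero and a ~30% deficit prevalence would be unreachable. With
these defaults the generative signal-to-total-variance ratio (the R² a
perfect model could reach) is ≈ 0.8 at n = 98; `calibrate_noise_sd`
computes the noise level for any target ratio exactly from the noise-free
cohort.

**Cohort composition.** Defaults emulate an acute stroke cohort: n = 98,
58% left-hemisphere lesions, ~30% deficit prevalence, 3-month follow-up
scores for ~76% of patients (follow-up = acute + independent noise, i.e., a
noisier retest). Prevalence is met by *targeting* a calibrated fraction of
left-hemisphere lesions at the eloquent peak: an initial fraction is set
from a closed-form ball-overlap approximation, then refined greedily on the
realized lesions until the expected prevalence under the noise model is
within 2 points of target (a configuration error is raised if the target is
unreachable by more than 10 points at the feasible extreme). Everything is a
pure function of (config, map): regeneration is bit-identical.

**Clustered cohort** (`generate_clustered_cohort`) serves the redundancy
analyses: four tight clusters of eight lesions each (per cluster: one
template shape, members are small frontier dilations of it that preserve the
rounded centroid — so members are mutually close under centroid,
topological *and* raw distance) plus six singleton lesions placed near the
grid centre, roughly equidistant from all clusters, with volumes *above*
the largest cluster volume. The volume ordering matters: the topological
distance between a small lesion and a larger one is ≈ √(volume difference),
so a small singleton would otherwise look spuriously redundant with a
cluster of similar volume. With flat distance rows the mean−SD threshold is
tie-sensitive; the cluster-vs-singleton count ordering holds across the
seeds exercised in the tests but is not guaranteed for every seed.

**What the generator does not emulate:** real MNI anatomy, vascular-territory
lesion shapes, registration or segmentation error, covariate structure
(age, education), and any nonlinearity in the lesion–behavior mapping. The
score model is linear in voxel space by construction, which favours the
linear models; passing tests therefore validate machinery and relative
behavior, not clinical-level accuracy on real data.

## Feature extraction (PCA)

PCA of the flattened masks is computed from the eigendecomposition of the
n × n centred Gram matrix and mapped back to voxel space — algebraically
identical to an SVD of the centred data matrix and far cheaper for
p ≈ 271k ≫ n. The retained count k is the smallest whose cumulative
explained-variance ratio reaches the threshold (default 0.95). Component
signs are fixed by making each component's largest-magnitude loading
positive.

By default PCA is refit inside every LOOCV training fold (no test leakage);
`pca_scope="whole-dataset"` reproduces the plausible original single-fit
pipeline. The harness evaluates per-fold PCA through Gram submatrices of
one precomputed cohort Gram matrix. Ridge penalties and RBF kernels are
invariant to the orthonormal basis of the fitted subspace, so this path is
prediction-equivalent to explicitly refitting PCA per fold (asserted in the
tests) while reducing the per-fold cost from O(n p) SVDs to O(n³)
eigendecompositions. For binary masks the float32 Gram accumulation is
exact (all partial sums are small integers).

## Predictors

All four models expose `Model(data...).fit() -> Results` with
`Results.predict` and `Results.summary()`; the LOOCV harness is
model-agnostic over this contract.

**Ridge.** Solved by SVD of the centred design (λ = 0 gives the minimum-norm
OLS limit); the intercept is unpenalized. λ is selected on the integer grid
1–150 by exact leave-one-out MSE using the identity e₍₋ᵢ₎ = rᵢ/(1 − hᵢᵢ)
computed from one SVD for all candidate λ; ties break toward larger λ
(more regularization).

**ε-SVR.** scikit-learn's libSVM backend solves the stated primal
(C = 50, ε = 0.1, RBF kernel). The stopping tolerance is tightened to 1e-8
so KKT conditions and primal/dual objective agreement hold to 1e-4 relative
(verified against an SLSQP solution of the dual QP in the tests). γ defaults
to 1/n_features. In the LOOCV harness SVR runs on the **raw flattened
images** by default, through a kernel precomputed from the cohort Gram
matrix (γ = 1/271633): on unscaled PCA coordinates, squared distances are
O(10³–10⁵) and the kernel underflows to a near-identity matrix, collapsing
SVR to an almost constant predictor (LOOCV r² 0.04 vs 0.71 for raw voxels on
the same synthetic cohort). A `input_mode="pca"` option retains the
PCA-feature variant.

**3D CNN.** Fixed architecture: conv (4 kernels 3×3×3, zero "same" padding)
→ ReLU → max pool 8×8×8 with stride 8 and partial edge windows included —
the only convention that yields 8 × 10 × 8 pooled maps from a 61 × 73 × 61
input — → 500-unit ReLU layer → sigmoid scalar. The conv layer has exactly
4·27 + 4 = 112 trainable parameters. Because the sigmoid cannot represent
negative scores, targets are affinely mapped from the training score range
onto [0.1, 0.9] (interior targets avoid saturation) and predictions are
inverse-mapped, clipping raw outputs to the invertible range; all-equal
training scores degrade gracefully to a constant predictor.

Implementation is plain numpy. The convolution is evaluated only on the
lesion's bounding box dilated by one voxel; outside it the pre-activation
equals the kernel bias, whose ReLU is folded into pooling analytically
(including the partial edge windows, tracked per pooling cell). Max-pool
gradients are routed to the arg-max voxels, with ties sharing the gradient
equally (a valid subgradient, deterministic). A dense scipy.ndimage forward
pass is kept as the reference implementation and the two are held equal in
the tests; analytic gradients are checked against finite differences.

Training: Adam (lr 1e-3, β 0.9/0.999), MSE loss, batch size 8, default 100
epochs, deterministic given the seed (fixed init and data order). Time-boxed
analyses (the end-to-end suite and `scripts/acceptance.py`) use 3 epochs per
LOOCV fold — chosen as the training budget for the 200-fold and 98-fold
cross-validations; the per-fold seed derives from the master seed and fold
index.

**Hybrid.** The fold-trained CNN's 500 fully-connected activations are
concatenated to the fold's k PCA features and passed to the same
λ-selected ridge. Within a fold the CNN is trained once and shared between
the CNN and hybrid predictions.

## Evaluation

LOOCV: n folds, each excluding one patient from PCA, λ search, and model
fitting; pooled held-out predictions are scored once. Accuracy is
r² = (Pearson r)² between actual and predicted, plus MAE. If either pooled
vector is constant, r² is reported as 0 with an explicit degeneracy flag.
Subgroup metrics (left-hemisphere, deficit score < 0, no-deficit score ≥ 0)
recompute the metrics on the filtered pool without retraining. Model
comparison uses a paired patient-level bootstrap (default 10,000 resamples):
patients are resampled jointly for both models, the r² difference
distribution yields an add-one two-sided p capped at 1. This is an
assumption-light substitute for an unspecified original test, not a
reconstruction of it.

## Redundancy

Three pairwise distances on masks: centroid (Euclidean between lesion
centroids, voxel units), topological (masks translated so rounded centroids
coincide — round half away from zero — cropped to the axis-aligned bounding
box of the larger-volume lesion, out-of-crop voxels treated as background,
then voxelwise Euclidean = √(disagreement count)), and raw (voxelwise
Euclidean in place). An image's redundancy count is #{j ≠ i : D[i,j] <
mean(row) − SD(row)}, with the self-distance excluded from the row
statistics and the count, population SD, strict inequality. Groups are a
median split on counts, ties to high; a split that leaves a group empty
(common when most counts are zero, e.g. weakly clustered cohorts) raises a
degeneracy error rather than fabricating a partition. Group metrics are
computed by restricting the full-cohort LOOCV predictions at scoring time,
not by retraining per group.

## Experiments

The scaling experiment draws, for each size in {25, 50, 75, 90} and each of
40 repeats (10 in the time-boxed acceptance script), a subsample without
replacement and runs the full LOOCV within it; subsample membership derives
deterministically from (master seed, size, repeat). The gap curve (reference
model r² minus CNN r², medians per size) is fit by a saturating exponential
a + b·exp(−c·size) with a linear fit alongside, and can be extrapolated to
size 150. The follow-up analysis restricts the cohort to patients with
3-month scores and reruns the identical pipeline on that column.

## Numerical choices and limitations

- Binarization tolerance on mask read: 1e-6 (resampled masks carry float dust).
- Ridge LOO identity guards h → 1 denominators at 1e-12.
- Gram eigenvalues below 1e-10 of the largest are treated as null space.
- The paired bootstrap treats pooled LOOCV predictions as independent across
  patients, ignoring the coupling induced by shared training folds.
- Pooled LOOCV r² is noisy and can sit well above 0 by chance at small n
  (visible in the permutation tests at n = 20–40); leakage conclusions are
  drawn at n = 200.
- The CNN at 3 epochs/fold is deliberately undertrained relative to the
  100-epoch default; it demonstrates the pipeline and the hybrid's use of
  its features, not the ceiling of CNN accuracy.
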