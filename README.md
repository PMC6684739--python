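# lesion2score

Predicting continuous language-deficit scores from 3D stroke lesion masks,
and measuring what that prediction depends on.

After a stroke, the severity of a language deficit depends on where the
lesion sits and how much eloquent tissue it destroys. Given a cohort of
binary lesion masks in a common 3 mm brain space (61 × 73 × 61 voxels) and a
continuous behavioral score per patient (negative = deficit), this package
compares four predictive models under leave-one-out cross-validation
(LOOCV), and quantifies how accuracy depends on training-set size and on the
redundancy of lesion patterns in the cohort. It is aimed at researchers in
lesion-symptom mapping and clinical neuroimaging ML.

The four models:

- **PCA + ridge regression** — masks are flattened to 271,633-dimensional
  vectors, reduced by PCA to the k components explaining 95% of variance,
  then fit by ridge regression minimizing Σᵢ(wᵀxᵢ − yᵢ)² + λ‖w‖₂², with λ
  chosen per fold on the grid {1, …, 150} by *exact* leave-one-out error
  (computed from one SVD via the linear-smoother identity, not n refits).
- **ε-SVR** — support vector regression minimizing ½‖w‖² + C·Σ(ξᵢ + ξᵢ*)
  with an ε-insensitive tube (C = 50, ε = 0.1) and RBF kernel
  K(x, x′) = exp(−γ‖x − x′‖²), γ = 1/n_features (libSVM via scikit-learn).
- **3D CNN** — one convolutional layer (four 3×3×3 kernels, ReLU), 8×8×8 max
  pooling to 8 × 10 × 8 maps, a 500-unit ReLU fully connected layer, and a
  sigmoid output; trained with Adam on MSE against scores rescaled into
  [0.1, 0.9]. Implemented in numpy, with a sparse bounding-box fast path for
  binary masks.
- **Hybrid** — ridge regression on the concatenation of the PCA features and
  the CNN's 500 fully-connected activations.

Accuracy is the squared Pearson correlation r² between pooled held-out
predictions and actual scores, plus mean absolute error (MAE). Redundancy of
an image is the number of other cohort images whose distance to it falls
below the row threshold mean − SD, under three distances (lesion-centroid,
centroid-aligned topological, and raw voxelwise Euclidean).

Real clinical cohorts of this kind are not shareable, so the package ships a
synthetic-cohort generator with a known ground truth: lesions grown by
random-walk dilation, and scores that decrease linearly in the lesion's
overlap with a fixed "language-eloquent" region, plus Gaussian noise. All
experiments run end-to-end on it.

## Worked example

```python
from dataclasses import replace
from lesion2score import (CohortConfig, calibrate_noise_sd, generate_cohort,
                          loocv, RidgeSpec, SVRSpec, compare_models, subgroup_eval)

base = CohortConfig(n_patients=98, seed=1)              # emulated acute cohort
noise = calibrate_noise_sd(base, target_r2=0.8)         # generative R^2 = 0.8
images, manifest = generate_cohort(replace(base, noise_sd=noise))

results = loocv(images, manifest, [RidgeSpec(), SVRSpec()], master_seed=1)
print(results["pca+rr"].summary())
print(results["svr"].summary())
left = subgroup_eval(results["pca+rr"], manifest, "left_hemisphere")
print(left.summary())
delta, p = compare_models(results["pca+rr"], results["svr"], seed=1)
print(f"ridge vs svr: delta r2 = {delta:+.3f}, p = {p:.4f}")
```

Output:

```
pca+rr [all] n=98  r2=0.605  MAE=1.819
svr [all] n=98  r2=0.599  MAE=2.159
pca+rr [left_hemisphere] n=57  r2=0.666  MAE=1.905
ridge vs svr: delta r2 = +0.006, p = 0.7091
```

Each patient's score was predicted by models trained on the other 97 (PCA
refit inside every fold); the ridge recovers ~0.6 of the score variance
against a generative ceiling of 0.8, accuracy rises slightly when restricted
to left-hemisphere patients (where the simulated eloquent region lies), and
the paired bootstrap finds no significant r² difference between the two
shallow models on this cohort.

A command-line interface mirrors the library:

```bash
lesion2score simulate --config cohort.yaml --out run/
lesion2score compare  --images run/masks --manifest run/manifest.csv --out run/cmp
lesion2score scaling  --images run/masks --manifest run/manifest.csv --out run/scal
lesion2score redundancy --images run/masks --manifest run/manifest.csv --metric raw --out run/red
```

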