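# Methods

## The problem

Volumetric breast density — the volume fraction of fibroglandular tissue
(FGT) in the breast, expressed in percent — is a strong risk factor for
breast cancer and a determinant of MRI screening policy. The conventional
way to quantify it on MRI is to segment the breast and the FGT and divide
the two volumes. `mridensity` implements a segmentation-free alternative:
a 3D regression convolutional neural network maps a non-fat-suppressed
T1-weighted breast volume directly to a single density percentage, is
trained against labels produced once by a fuzzy-c-means (FCM) pipeline, and
is explained voxel-by-voxel with Shapley-additive attributions so a reader
can check *where* the network looked.

Because patient MRI volumes cannot be redistributed, the package ships a
synthetic phantom generator with analytically known density and exercises
the entire method on it. Everything below is therefore measurable end to
end inside the test suite.

## Phantom model

A phantom is laid out on an isotropic voxel grid (default 48³ at
1.35 mm spacing) with a fixed axis convention: axis 0 left–right, axis 1
anterior→posterior, axis 2 superior→inferior.

* **Breast**: a half-ellipsoid strictly anterior of the chest-wall
  (sternum) plane at 58 % of the AP extent. Semi-axes default to ≈29 % of
  the grid per axis and vary phantom-to-phantom (factors 0.85–1.05) in
  cohorts.
* **Confounders**: a pectoral-muscle slab immediately posterior of the
  chest wall (8 % of the AP extent thick) and a heart-like ellipsoid in the
  posterior-inferior chest. These exist so that attribution maps have
  plausibly wrong places to put mass.
* **FGT**: a white-noise Gaussian field smoothed to a correlation length of
  5 mm (the scale of fibroglandular strands) and thresholded at its
  empirical (1 − d/100) quantile inside the breast. Top-k selection makes
  the realized density exact up to the integer voxel count, so
  `true_density = 100·|FGT|/|breast|` holds identically — this is the
  property that makes the phantom a usable oracle.
* **Intensities**: compartment means (arbitrary units) air 0.05, FGT 0.30,
  muscle 0.35, heart 0.40, fat 0.85 — encoding the fat-bright/FGT-dark
  contrast of non-fat-suppressed T1 imaging. The chest bulk renders at the
  fat mean. Corruption: a random cubic polynomial bias field rescaled to
  span exactly [1−A, 1+A] (default A = 0.2) multiplies the image, and
  Gaussian noise (default σ = 0.05, i.e. ≈9 % of the fat–FGT gap) is
  added. All randomness derives from one spec seed.

What the phantoms do **not** model: bilateral anatomy, coil-sensitivity
physics, contrast dynamics, skin, vessels, partial-volume mixing at tissue
interfaces, or anatomically realistic FGT morphology. Passing tests
therefore demonstrate that the *method* is implemented correctly and can
recover a known signal under realistic corruption levels — not that the
trained weights transfer to patient scans.

## Preprocessing

1. **Bias correction** (default `surrogate_polynomial`): a polynomial of
   total degree ≤ 3 is least-squares fit to the log-intensities of the
   brighter half of the foreground (foreground = voxels above 25 % of the
   97.5th percentile). Restricting the fit to the bright (fat-like) class
   keeps the dark FGT from dragging the field estimate. The exponentiated
   fit is divided out and the gain re-anchored to the foreground mean.
   Intensities must be positive; `shift="auto"` offsets a volume that
   touches zero and removes the offset afterwards. `external_n4` delegates
   to SimpleITK's N4 instead. The residual inhomogeneity after correcting a
   known cubic field is ≤ 2 % once the global gain — which the next step
   absorbs anyway — is factored out.
2. **Normalization**: per-volume rescale to [0, 1] between the 2.5th and
   97.5th intensity percentiles with clipping, linear-interpolation
   quantile convention. Per-volume (rather than per-dataset) windows keep
   inference on a single new scan self-contained.
3. **Crop**: the recorded breast box — centered on the breast left–right
   and superior–inferior, and on the sternum plane anterior–posterior, so
   confounders remain in view — is cut out and zero-padded/center-cropped
   to the model input shape.

The pipeline order bias → normalize → crop is recorded in each volume's
provenance.

## Ground truth

FCM with 2 clusters and fuzziness m = 2 clusters the breast-interior
intensities; the cluster with the lower centroid is FGT (fat is bright).
A voxel is FGT iff its FGT membership exceeds 0.5 (ties to fat — the
conservative direction). Centroids are initialized by a seeded
k-means++-style spread; convergence is a centroid shift below 1e-6, and
non-convergence is reported, never silent. The density label is
100·|FGT|/|breast| after clearing everything at or posterior of the sternum
plane; fuzzy (membership-sum) counting is available but hard counting is
the default.

Degenerate breasts (a single tissue class, e.g. a fat-only breast plus
noise) would otherwise be split down the middle of the noise distribution;
a centroid separation below 0.15 normalized-intensity units instead returns
an empty FGT mask with a `LowSeparationWarning`. At very low densities
(≲ 4 %) the clustering occasionally collapses this way, producing a
zero label — label noise of the same kind the clustering pipeline produces
on real scans, and one reason both the FCM label and the analytic truth are
recorded side by side.

The dense/non-dense subgroup analysis requires at least 3 samples in each
subgroup; a threshold at or outside the observed density range raises an
error rather than silently reporting a one-group result.

## Network and training

Input volume (production 128³, tested desk setting 32³) → five 3×3×3
convolutions with stride 2×2×2, "same" padding, PReLU activations
(one learned negative-side slope per channel) and 50 % dropout; filter
counts (f0, 2f0, 4f0, 4f0, 4f0) — doubling in the second and third layer,
held constant afterwards since nothing dictates further growth; → flatten →
two dense layers of 128 with PReLU and dropout → linear scalar output.
Spatial extent halves (ceiling division) per layer: 128³→4³, 32³→1³.

The engine is written in numpy with hand-derived backprop; every layer's
gradient is tested against central finite differences. Training minimizes
mean absolute error with Adam (β₁ = 0.9, β₂ = 0.999) on the density
percentage, with on-the-fly augmentation — integer translations up to the
configured maximum on the left–right and superior–inferior axes only (the
chest wall anchors the AP direction) and rotations up to 10° about the
sagittal and transversal axes, linear interpolation, constant fill. The
weights retained are those of the best-validation epoch. All randomness
(init, batch order, dropout, augmentation) derives from the config seed.

Hyperparameters: the random search draws the starting filter count
uniformly from {4..32} and the learning rate log-uniformly from
[1e-8, 1e-2], scoring each trial by validation MAE with first-sampled
tie-breaking. Defaults outside the search: learning rate 1e-3 (higher
values destabilize MAE/Adam training at desk scale, lower values
under-train), batch size 8, and 600 epochs at the 32³ desk scale — the validation error
is still clearly improving at 150 epochs and plateaus around epoch 550,
and best-validation checkpointing makes extra epochs safe. A step
learning-rate decay is available (`lr_decay_every`/`lr_decay_factor`) but
off by default: on the desk experiment an early decay freezes the model
before the validation error has bottomed out. Predictions are reported raw
(unclamped); clamping to [0, 100] is a flag.

The split is deterministic on ranked id: first block train, then
validation, then hold-out test (desk default 140/20/40 of 200), mirroring a
split on ranked study number; exchangeability of the partitions is checked
with Kruskal–Wallis (continuous covariates) and χ² (categorical) tests.

## Attribution

DeepLIFT rescale-rule backpropagation against a background volume: linear
and convolutional layers propagate multipliers through their weights (the
bias-free transpose), each PReLU multiplies by the secant slope
(f(aₓ)−f(a_b))/(aₓ−a_b) between the pre-activations of the explained input
and the background, falling back to the local derivative when
|aₓ−a_b| < 1e-7. Contributions are C = m ⊙ (x−b) at the input; by
construction they satisfy summation-to-delta, ΣC = f(x)−f(b), which the
tests verify against two forward passes on random networks and on the
trained model (tolerance 1e-3 relative + 1e-6 absolute). The Deep-SHAP map
averages the per-background contributions over 15 volumes sampled without
replacement from the training set (averaging after backprop — the order
matters on nonlinear nets); its base value is the mean model output over
the backgrounds, and the completeness residual is stored on the map.
Positive voxels push the density estimate up.

**QC statistic**: the fraction of total |SHAP| mass inside the breast mask.
An estimate with inside-fraction below 0.8 (a configurable default, not an
empirical constant) is flagged as leaning on confounders. The
`confounder_challenge` experiment makes this measurable: fresh phantoms
whose muscle/heart intensities are drawn far outside the training
distribution produce both correct and badly wrong estimates, and the test
asserts that the wrong ones carry less attribution mass inside the breast.

## Evaluation

Spearman rank correlation (midrank ties, large-sample p) between estimates
and ground truth; nonparametric Bland–Altman agreement with differences
taken as estimate − ground truth: median bias and 2.5th/97.5th-percentile
limits of agreement, same quantile convention as preprocessing so all
percentile code shares one oracle. Subgroup correlations split on the
ground-truth density at 15.5 % (a literature convention for the
dense/non-dense boundary, configurable).

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics, everywhere.
* FCM: a sample coincident with a centroid receives full membership there
  (split evenly over coincident centroids); the objective is asserted
  non-increasing in tests.
* Normalization rejects constant volumes (zero-width window); re-applying
  it moves only the clipped tails.
* Dropout is inverted (expectation-preserving) and inactive at inference;
  attribution and prediction are bit-deterministic.
* An all-zero attribution map makes the inside-fraction undefined; it is
  reported as degenerate and flagged rather than silently 0/0.
* Cohort, FCM, CNN, background-sampling and QC seeds all derive
  deterministically from one master seed; re-running an experiment with the
  same config reproduces the metrics exactly.

## Desk-scale problem sizes

The package's standard experiment — the one `scripts/acceptance.py`
re-runs — uses 200 phantoms at 48³ rendered and cropped to 32³ model
inputs, densities uniform in [2, 40] % (the range typical of volumetric
breast density), a 140/20/40 ranked-id split, 15 SHAP backgrounds, and a
50-phantom confounder challenge. The augmentation translation is 5 voxels
at 32³, the proportional counterpart of 20 voxels at the production 128³.
These sizes keep a full run in the ten-minute range on a single CPU while
leaving every statistic well-defined; the 128³ production configuration is
the same code path with a different config.

## Known limitations

* The phantom's FGT texture is a thresholded Gaussian field, not anatomy;
  Dice values against construction truth are optimistic relative to
  clinical inter-reader variability.
* The surrogate polynomial bias corrector estimates the field from the
  bright tissue class only and removes global gain up to a constant; it is
  not a reimplementation of N4 (which is available behind the
  `external_n4` flag).
* Training at 128³ is supported by the code but not exercised by the test
  suite; the numpy engine is single-threaded BLAS-bound and not meant for
  GPU-scale runs.
* The hold-out statistics on phantoms characterize the implementation, not
  clinical performance.
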