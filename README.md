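# mridensity

Segmentation-free volumetric breast density estimation on MRI-like volumes,
with voxel-wise explanations.

Volumetric breast density — the percentage of the breast occupied by
fibroglandular tissue (FGT) — is usually quantified on MRI by segmenting
the breast and the FGT and dividing the two volumes. `mridensity`
implements the segmentation-free alternative: a 3D regression
convolutional neural network maps a non-fat-suppressed T1-weighted volume
directly to the density percentage

d = 100 · |FGT| / |breast|  [%],

is trained once against labels from a fuzzy-c-means (FCM) clustering
pipeline, and is explained per voxel with Shapley-additive attributions
(Deep SHAP via DeepLIFT-rescale backpropagation), so a reader can verify
that an estimate rests on breast tissue rather than on the pectoral muscle
or the heart. Agreement with ground truth is assessed nonparametrically:
Spearman's ρ, median bias, and percentile (2.5/97.5) limits of agreement.

Because patient volumes cannot be shipped, the package includes a synthetic
phantom generator whose density is exact by construction; the whole method
is exercised end to end on those phantoms. The intended audience is
researchers in quantitative breast imaging who want a fully inspectable,
dependency-light reference implementation of the approach.

The network (five 3×3×3 stride-2 convolutions with PReLU and 50 % dropout,
filters f0, 2f0, 4f0, 4f0, 4f0; two dense layers of 128; linear output;
MAE loss, Adam) and the DeepLIFT/Deep-SHAP attribution are implemented in
numpy with hand-derived, finite-difference-verified backprop — the
attribution needs the layer internals anyway.

## Worked example

```sh
# 1. simulate a small cohort (NIfTI volumes + masks, labels.csv, manifest)
mridensity simulate --n 10 --seed 5 --outdir cohort/

# 2. ground-truth density of one phantom from its volume + breast mask
mridensity groundtruth --volume cohort/p0000.nii.gz \
    --breast-mask cohort/p0000_breast.nii.gz --sternum-index 29 \
    --out label.json
```

which prints, for example,

```
density = 23.51%
```

the FCM-derived volumetric density of that phantom: 23.51 % of the breast
voxels cluster as fibroglandular. In Python, the full experiment — cohort,
FCM labels, preprocessing (polynomial bias correction, 2.5/97.5-percentile
normalization, crop), ranked-id split 140/20/40, CNN training,
hold-out prediction, evaluation, and Deep-SHAP QC — is one call:

```python
from mridensity.experiment import ExperimentConfig, run_experiment

results = run_experiment(ExperimentConfig(master_seed=17), "outdir")
print(results["metrics"])
```

At the pinned seed 17 this prints (abridged):

```
spearman_rho: 0.933    median_bias: -0.67
loa_low: -7.7          loa_high: 6.5
test_mae: 3.49         n_test: 40
```

Read: on the 40 hold-out phantoms the estimated density tracks the
ground-truth density with rank correlation 0.93; the estimator runs
0.7 percentage points low at the median, and 95 % of differences fall
between −7.7 and +6.5 percentage points. `outdir/` also receives the
per-phantom SHAP overlay PNGs and a `qc.json` with each explained
estimate's inside-breast attribution fraction.

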