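# femurseg

A pure-Python (NumPy) toolkit for volumetric proximal-femur MR segmentation
with encoder–decoder CNNs, built to be trainable and testable on CPU using
synthetic femur-like phantom volumes.

Components:

- **`femurseg.core_io`** — domain types (`ImageVolume`, `LabelMask`,
  `ProbabilityMap`), NIfTI-1 reading/writing via nibabel, bicubic in-plane
  resampling with field-of-view-preserving spacing rescale, YAML run
  configuration and structured run logs.
- **`femurseg.phantom`** — synthetic femur-like phantoms: a sphere (head) +
  two cylinders (neck at a configurable neck–shaft angle, shaft) rasterized
  on an anisotropic grid, bright marrow with band-limited trabecular texture
  on a darker background, a darkened cortical rim, Gaussian noise, and
  optional fold-over (aliasing) and intra-bone lesion corruptions. Cohort
  generation attaches laterality and a binary stratum label for stratified
  cross-validation.
- **`femurseg.nets`** — 2D/3D encoder–decoder (U-shaped) networks, padded or
  unpadded (2D only), with an optional dilated-convolution pyramid center
  whose per-rate outputs are concatenated along channels. Xavier
  initialization, biases 0.10, ReLU activations, softmax head; forward *and*
  backward passes are implemented in NumPy (`femurseg._nn`), plus the
  analytic shape algebra (`output_shape`, `receptive_field`) and checkpoint
  save/load with the architecture spec embedded.
- **`femurseg.training`** — class-re-weighted cross-entropy (per-sample
  foreground/background weights `N_b/N`, `N_p/N`), joint horizontal-flip
  augmentation, three-slice 2D sampling, stratified k-fold assignment, Adam
  optimization with warmup + patience early stopping, and cross-validation.
- **`femurseg.inference`** — mirrored tiled inference with overlap averaging
  for unpadded 2D models, direct padded prediction (2D per slice stack / 3D
  whole volume), strict-threshold binarization, largest-connected-component
  post-processing (2D default on, 3D default off), and bicubic upsampling of
  probability maps back to an original grid.
- **`femurseg.metrics`** — confusion-based overlap metrics (DSC, precision,
  recall, specificity), exact-Euclidean average/maximum symmetric surface
  distances in mm, ROC/PRC curves with trapezoidal AUC and step-wise AP,
  PRC operating-point selection (closest point to precision=recall=1),
  paired Wilcoxon signed-rank tests with Holm correction, and per-subject /
  aggregate reporting.
- **`femurseg.cli`** — `femurseg` command with `simulate`, `train`, `cv`,
  `predict`, `evaluate` and `compare` subcommands, global-seed fan-out and
  machine-readable run records.

## CLI quick start

```sh
# 8 phantoms with paired ground-truth masks and a manifest CSV
femurseg simulate --n 8 --seed 0 --out runs/sim

# 2-fold cross-validation of a small 3D network
femurseg cv --manifest runs/sim/manifest.csv --out runs/cv \
    --k 2 --dims 3 -F 4 -L 2 --max-epochs 5 --learning-rate 1e-3 --seed 0

# single-volume prediction from a fold checkpoint
femurseg predict --checkpoint runs/cv/fold0_model.npz \
    --volume runs/sim/phantom000_image.nii --out runs/pred --threshold 0.5

# evaluation and model comparison
femurseg evaluate --manifest runs/eval_manifest.csv --out runs/eval
femurseg compare --table ap_modelA.csv --table ap_modelB.csv --out runs/cmp
```

Every flag can also be supplied through a YAML config (`--config`, see
`femurseg.core_io.RunConfig`).

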