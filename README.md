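# rotomics

Rotation-robustness auditing of 3D radiomic texture features: how much do
wavelet-decomposition (WD) features — versus non-WD features — change when a
lesion is rigidly rotated before extraction, and how much does that movement
cost a classifier trained on unrotated data?

The package implements the full study loop on **synthetic CT-like phantoms**
(no external data needed):

1. **`rotomics.phantoms`** — ellipsoidal lesions with paired masks, oriented
   or isotropic texture, three texture classes, optional spurious mask
   islands; NRRD/NIfTI I/O and CSV cohort manifests.
2. **`rotomics.preprocess`** — Otsu-foreground z-scoring, <10-voxel island
   removal, pair validation, isotropic resampling to the cohort's modal
   spacing, bounding-box cropping, fixed-bin-width discretization.
3. **`rotomics.rotation`** — per-patient rotation sets R0…R80: deviation
   angles drawn as |N(label°, 10°)| about uniformly random axes, applied
   about the mask center of mass (trilinear image / nearest mask); R0 passes
   through the identical resampling path with the identity transform.
4. **`rotomics.filterbank`** — 18 channels per lesion: original, 8 one-level
   undecimated Coif1 wavelet components (exact FFT-domain filtering, perfect
   reconstruction), Laplacian of Gaussian, square / squareroot / logarithm /
   exponential, gradient magnitude, and 3 spherical local-binary-pattern maps
   (m1, m2, k).
5. **`rotomics.features`** — 93 texture features per channel (18 first-order,
   24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM; IBSI-aligned definitions)
   plus 14 mask-only shape features → 1674 texture features per patient
   (744 WD + 930 non-WD).
6. **`rotomics.stability`** — per-feature percentage differences vs R0,
   per-rotation-set IQRs with Student-t CIs, pooled Spearman correlation of
   |%Δ| against rotation degree with effect-size strata
   (trivial/weak/moderate/strong at |CC| = 0.1/0.3/0.7), and filter×category
   heat-map tables.
7. **`rotomics.modeling`** — WD-only vs non-WD 3-class models: all-sample
   preliminary filtering, per-fold Kruskal–Wallis + L1-multinomial fine
   selection, five classifiers (KNN, logistic, random forest, linear/RBF
   SVM), repeated stratified 5-fold CV (default 50×5 = 250 cycles) trained on
   R0 and tested on R0…R80, and Spearman trend tables of
   accuracy/macro-F1/sensitivity/specificity vs rotation.

## Command-line pipeline

```bash
rotomics all --seed 7 --outdir out --n-patients 30        # full study
rotomics simulate --config my_config.yaml                 # single stages:
rotomics extract  --config my_config.yaml                 #   simulate |
rotomics stability --config my_config.yaml                #   extract |
rotomics model    --config my_config.yaml                 #   stability | model
```

Outputs land in `--outdir`: cohort volumes + manifest, rotation manifest,
`features.csv` (long format), stability records and Fig-3/4-style tables
(`heatmap_iqr.csv`, `heatmap_pct_significant.csv`,
`lineplot_iqr_by_label.csv`), CV records and trend tables
(`cv_records.csv`, `trend_table.csv`, `accuracy_by_label.csv`). Every output
directory is stamped with the resolved config and its hash; rerunning with a
different config in the same directory fails loudly.

A YAML config mirrors all module options (see `tests/test_cli.py` for a
working example); CLI flags `--seed/--outdir/--n-patients/--repeats`
override it.

## Notes

All volumes here are synthetic stand-ins: simple ellipsoids with parametric
texture. They carry the statistical structure the analysis needs
(orientation-bearing texture, partially texture-borne class labels,
anisotropic voxels) but make no claim to CT realism.
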