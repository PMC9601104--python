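# radres

How does tumour-segmentation accuracy propagate into MRI delta-radiomic
outcome models?  `radres` implements the full analysis chain as a tested,
reusable pipeline:

- **`radres.cohort`** — seeded synthetic imaging cohorts: paired baseline /
  follow-up two-channel lesion volumes with ground-truth masks,
  class-dependent growth and texture change (local control vs local
  failure), a patient-level train/val/test split, and outcome-linked
  progression-free-survival records.
- **`radres.masks`** — segmentation quality metrics (Dice, Hausdorff
  distance, volume estimation error) and `perturb_to_target_dice`, which
  degrades a mask to a prescribed Dice level (boundary noise, morphological,
  or random-field deformation modes), emulating segmentation models of
  differing accuracy.
- **`radres.cascade`** — cascade segmentation orchestration (slice-mask OR
  reduction, connected-component centring, nested crops, probability-map
  fusion) over pluggable slice/volume segmenter backends; a classical
  intensity backend is included.
- **`radres.features`** — radiomic feature extraction: 19 first-order, 26
  shape (17 3D + 9 2D), and GLCM/GLRLM/GLSZM/NGTDM/GLDM texture families
  (24/16/16/5/14 features) over the original image and its 8 stationary
  coif1 wavelet sub-bands, for two modalities and tumour + 5 mm margin ROIs
  — exactly 3436 features per lesion-timepoint — plus relative-difference
  delta features between timepoints.
- **`radres.mrmr`** — minimum-redundancy maximum-relevance selection
  (quotient criterion: F-statistic relevance / mean |Pearson| redundancy).
- **`radres.outcome`** — RBF-kernel SVM (C=1, gamma=1/num_features,
  tol=1e-3, inverse-frequency class weights) with train-set min–max
  normalization and an accuracy/sensitivity/specificity/AUC/F1 report.
- **`radres.survival`** — Kaplan–Meier curves, the two-group log-rank test,
  and patient stratification by predicted outcome.
- **`radres.experiment`** — the paired robustness study: for each
  segmentation-quality level (ground truth, Dice 0.90/0.88/0.85/0.80 by
  default) run perturbation → extraction → delta → selection → SVM →
  survival on the same cohort, and report feature overlap with the
  ground-truth pipeline and metric degradation.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force enumeration oracles for every texture
matrix, an independent greedy implementation of the mRMR rule, comparisons
against `lifelines`/`scikit-learn` for the survival and AUC machinery, and
scaled-down stochastic acceptance tests of the full robustness study
(`tests/test_acceptance.py`).

## CLI

`radres` groups the pipeline stages:

```bash
radres simulate --seed 0 --out cohort/           # synthetic cohort (NIfTI + CSV)
radres perturb  --mask m.nii.gz --target-dice 0.85 --out p.nii.gz
radres extract  --t1 t1.nii.gz --t2 t2.nii.gz --mask m.nii.gz --out feats.csv
radres select   --features train.csv --labels labels.csv --k 7 --out sel.json
radres train    --train train.csv --labels labels.csv --select sel.json --out model.joblib
radres evaluate --model model.joblib --test test.csv --labels labels.csv
radres survival --records survival.csv --cohorts cohorts.json
radres run      --seed 42 --out results/         # full robustness study
```

Standalone commands `mask-eval`, `mask-perturb`, `cascade-run`, `mrmr`,
`outcome-train` and `outcome-eval` expose the individual modules.
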