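# radpipe

A tested, reusable MRI radiomics pipeline for predicting a binary
progression/recurrence outcome from two co-registered pre-operative MR
channels (contrast-enhanced T1-like and T2-like):

1. **synthetic_cohort** — phantom cohort generator: two-channel 3D volumes
   with a contiguous hyperintense tumor whose higher-order texture
   (intensity skewness, size-zone granularity) differs by outcome class,
   clinical covariates, and exponential-hazard time-to-event outcomes with
   uniform administrative censoring. Everything downstream is testable
   without any external imaging data.
2. **segmentation** — slice-wise two-cluster fuzzy c-means inside an
   operator seed box, largest 26-connected 3D component, hole filling, and
   affine mapping of the mask onto the second channel's grid.
3. **features** — 107 radiomic features per modality (14 shape +
   18 first-order intensity + 24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM +
   14 GLDM), 214 per patient, with fixed-bin-count discretization and
   3D distance-1 texture matrices (13 directions / 26-neighborhoods; a 2D
   per-slice mode is available).
4. **svm_scoring** — per-patient risk score from the Gaussian-kernel SVM
   expansion `f(x) = Σ wₙ yₙ exp(−‖xₙ−x‖²) + b` on z-scored features, with
   sequential forward feature selection driven by repeated stratified
   10-fold cross-validation (improvement threshold 1e-6, default maximum
   of four features). Scores are out-of-fold by default; the pipeline's
   selection objective defaults to CV AUC (accuracy is configurable but
   degenerates at the default ~15% event prevalence).
5. **outcome_stats** — ROC/AUC with the Youden-optimal cutoff
   (positive when score > cutoff), chi-square / Fisher / Mann-Whitney group
   comparisons, Kaplan-Meier + log-rank, univariate→multivariate Cox with a
   p < 0.05 gate, and ICC(2,1) agreement.
6. **pipeline / cli** — end-to-end orchestration with a YAML config, a
   frozen per-run config copy, stage-level logging, and NIfTI/CSV I/O.

## CLI

```bash
radpipe schema                                   # print all config fields
radpipe simulate --n-patients 128 --seed 1 --out cohort/
radpipe segment --t1c cohort/images/P0000_t1c.nii.gz \
    --t2 cohort/images/P0000_t2.nii.gz \
    --box 3 8 5 35 5 35 --out mask.nii.gz
radpipe extract --t1c ... --t2 ... --mask mask.nii.gz --out features.csv
radpipe select --features features.csv --covariates cohort/covariates.csv \
    --out selected.json
radpipe evaluate --scores run/scores.csv --covariates cohort/covariates.csv \
    --out eval.json
radpipe run-all --n-patients 128 --seed 1 --out runs/demo
```

`run-all` writes `covariates.csv`, `features.csv` (214 columns),
`scores.csv`, `selected_features.json`, `cox.csv`,
`group_comparisons.csv`, `summary.json`, the frozen `config.yaml` and a
`run.log` into the run directory. Two runs with the same config and seed
produce identical outputs.

## Python API sketch

```python
import radpipe as rp

pair, truth, latent = rp.generate_phantom_pair(rp.PhantomSpec(), class_label=1, seed=7)
mask = rp.segment_volume(pair, box)          # or use the truth mask
vec = rp.extract_feature_vector(pair, mask, mask)      # 214 named values

patients, table = rp.simulate_cohort(128, seed=1)
out_dir = rp.run_pipeline(rp.RunConfig(n_patients=128, seed=1))
```
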