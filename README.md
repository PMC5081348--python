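# saccdecode

ROI-based multivoxel decoding of saccade amplitude from simulated
block-design fMRI.

The package re-implements, as a tested and reusable pipeline, an analysis
showing that multivoxel activity patterns in the frontal and parietal eye
fields discriminate the execution of large (30°) from small (4°) saccades,
while the supplementary eye field and inferior precentral cortex do not.
Because no recordings are deposited for that experiment, a first-class
synthetic-data layer generates every input with known ground truth, so each
stage of the analysis is exercisable offline:

1. **Design generation** (`saccdecode.design`) — 36 four-second mini-blocks
   per run (6 condition types × 6 repeats: {small, large, mixed} × {left,
   right}), ordered by a balanced Eulerian-path construction so every
   condition follows every other near-equally; 6–8 s jittered fixation gaps,
   8 s lead/trail fixation; six targets per block at exactly 1.5 Hz.
2. **Eye-trace simulation** (`saccdecode.oculo`) — 60 Hz horizontal gaze
   with main-sequence kinematics (V = vmax·(1 − e^(−A/a0))), latency,
   amplitude-proportional endpoint scatter, corrective saccades, optional
   blink/violation injection for QC testing.
3. **Eye QC** (`saccdecode.qc`) — threshold-based saccade detection
   (deviations > 2° from the running fixation median), amplitude classes
   small [2–6] / medium (6–15) / large (> 20), block validation against the
   stimulus schedule, and block / run / subject exclusion rules (> 50%
   invalid).
4. **ROI atlas** (`saccdecode.atlas`) — eight connected masks of published
   sizes (564 SEF … 1043 parietal voxels) grown inside published stereotaxic
   bounding boxes on a 2 mm standard-space grid; NIfTI round-trip.
5. **BOLD simulation** (`saccdecode.bold`) — double-gamma HRF, per-ROI
   condition-specific multivoxel patterns over an informative voxel
   fraction, AR(1) noise, baseline and drift; full ground-truth record.
6. **GLM** (`saccdecode.glm`) — Gaussian-weighted running-line high-pass
   filter (σ = 50 s), per-block (beta-series, 79 columns) and per-condition
   (19 columns) design matrices with temporal derivatives and motion
   regressors, OLS, contrasts (large − small; mixed − same-size), 5 mm FWHM
   smoothing for the univariate branch.
7. **MVPA** (`saccdecode.mvpa`) — run-wise mean-centering, linear SVM
   (C = 1, deterministic), leave-one-run-out cross-validation, univariate
   ("all saccades > rest") feature selection computed on training runs only,
   and accuracy-vs-ROI-size curves (200 … 900 voxels).
8. **Inference** (`saccdecode.inference`) — exact one-sample t vs 50%
   chance, 10,000-fold sign-flip max-t permutation across the eight ROIs
   (family-wise α = 0.05; exhaustive enumeration for small n), paired
   behavioural tests, and within-ROI voxelwise permutation contrasts.
9. **Pipeline + CLI** (`saccdecode.pipeline`, `saccdecode.cli`) — one-config
   orchestration with a structured JSON report and figure generation.

## Run the tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (null calibration, FWER control, permutation and SVM oracles,
effect recovery, design balance, QC exactness, GLM recovery).

## CLI

Run everything from one YAML config (all sections optional; see
`saccdecode.pipeline.PipelineConfig` for the schema):

```bash
saccdecode all --config config.yaml --out results/run1 --seed 7
```

which writes `accuracy.tsv`, `roi_stats.tsv`, `qc.tsv`, `contrasts.tsv`,
`report.json`, figures and a config echo. Stages can also be run
separately on artifact directories:

```bash
saccdecode simulate --config config.yaml --out data/
saccdecode qc       --traces data/ --events data/ --out qc.tsv
saccdecode glm      --bold data/ --events data/ --out betas/
saccdecode mvpa     --betas betas/ --events data/ --atlas data/atlas.nii.gz \
                    --qc qc.tsv --out accuracy.tsv
saccdecode infer    --accuracy accuracy.tsv --out roi_stats.tsv
saccdecode figures  --report results/run1
```

The default 17-subject, 5-run configuration completes in about one minute
on a single CPU.

## Notes on scope

The original study's headline decoding accuracies and Z values were
computed from human data that is not publicly available; the synthetic
defaults are calibrated to reproduce the qualitative result (parietal and
FEF informative, SEF and precentral not) with realistic effect sizes, not
to match those exact numbers. FSL-specific preprocessing (motion
correction, prewhitening, mixed-effects variance modelling, registration)
is out of scope; estimation is OLS on data simulated directly on a common
standard-space grid.
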