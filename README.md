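# neurofuse

Multimodal brain-map diagnostic classification: cross-validated unimodal
machine learning on voxel maps, redundancy scoring of the predictive
information shared between map types, and three multimodal integration
strategies — probability-based late fusion, two-step sequential voxel
selection, and a voxel-level 1D-convolutional channel-mixing network.
A synthetic multimodal cohort generator with controllable shared-signal
structure makes the full pipeline testable without any imaging data.

## Package layout

| module | purpose |
| --- | --- |
| `neurofuse.cohort` | synthetic multimodal cohorts: two groups, per-modality signal voxel sets with a pairwise-sharing dial, additive age/sex effects |
| `neurofuse.map_io` | NIfTI volumes and masks, mask intersection, block-mean downsampling, flat subject × voxel matrices (fixed C-order voxel identity) |
| `neurofuse.confounds` | per-voxel OLS removal of age/sex effects, fitted on training rows only |
| `neurofuse.crossval` | stratified 10-fold engine, four classifier families (ridge, lasso, random forest, gradient boosting), accuracy summaries with bootstrap CIs |
| `neurofuse.redundancy` | conditional success probabilities and redundancy scores between map types from pooled test-set correctness |
| `neurofuse.fusion_probability` | mean / most-confident / logistic-stack fusion of unimodal outcome probabilities |
| `neurofuse.fusion_twostep` | per-fold voxel selection (top-20% coefficients or nonzero importances), merged refit, selection-overlap statistics |
| `neurofuse.fusion_cnn` | width-1 1D convolution across modality channels + dense ReLU layer + softmax, trained with SGD/momentum |
| `neurofuse.cli` | YAML-config orchestration (`run_experiment`) and the `neurofuse` CLI |

All strategies reuse one `FoldPlan`, so per-subject correctness indicators
are comparable across modalities and fusion strategies, and every
training-derived quantity (confound models, standardization, penalties,
voxel selections) is computed inside each fold from training rows only.

## CLI

```bash
# write an experiment config
cat > config.yaml <<'YAML'
seed: 1
output_dir: results/demo
cohort:
  spec:
    n_voxels: 1000
    signal_count_per_modality: 150
    effect_size_per_modality: 0.3
folds: {n_folds: 10}
families: [ridge, lasso]
strategies: [unimodal, redundancy, probability, twostep, cnn]
YAML

neurofuse simulate --config config.yaml --out cohort_dir   # materialize cohort (CSV)
neurofuse run-all  --config config.yaml                    # full experiment
neurofuse report   --results results/demo                  # accuracy table
```

Subcommands `unimodal`, `redundancy`, `fuse`, `twostep`, `cnn` run subsets.
The result bundle contains `predictions.csv` (per-subject probabilities and
correctness for every source × algorithm), `accuracy_summary.csv`,
`redundancy_<family>.csv/json`, overlap tables, selection masks, CNN loss
curves, and a `manifest.json` recording seeds, config hash and per-stage
status (a failing strategy is recorded there without aborting the rest).

## Tests

```bash
python -m pytest tests/          # full suite, ~6 minutes
```

`tests/test_acceptance.py` holds the acceptance criteria: analytic chance
levels (4% selection overlap, 0.5 coin-flip accuracy), redundancy-score
limits against a brute-force contingency oracle, monotone recovery of the
shared-signal dial, the complementarity benefit of two-step fusion on
disjoint signals, null calibration of every family and fusion strategy, CNN
architectural contracts, and fold-hygiene (no test-row leakage into any
training-derived state).

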