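# somatomap

Finger-somatotopy analysis of primary somatosensory cortex on synthetic BOLD
data: travelling-wave (phase-encoded) winner-take-all mapping, split-half Dice
consistency, blocked-design GLM with percent-signal-change extraction,
crossnobis representational similarity analysis (separability, typicality,
MDS), and the accompanying single-case / bootstrap / rank statistics.

No external data are required: the `synth` module generates cohorts (controls,
SCI patients with graded somatotopic deterioration, one-handers) with known
ground truth, so every analysis stage is testable end to end.

## Layout

| module | contents |
|---|---|
| `somatomap.synth` | synthetic cohort generator: Gaussian finger tuning on a thumb-to-little gradient, deterioration parameter, AR(1)-optional noise |
| `somatomap.design` | acquisition designs (travelling-wave: 10 s/finger, 50 s cycle, 7 cycles, 182 volumes at TR 2 s; blocked: 8 s blocks, 5 conditions + rest, 127 volumes) and HRF-convolved regressors |
| `somatomap.hrf` | gamma / double-gamma response kernels |
| `somatomap.travelwave` | 25-lag reference-model bank, per-voxel lag cross-correlation with Fisher r-to-z, finger/lag winner-take-all maps, FDR thresholding, group probability maps |
| `somatomap.dice` | split-half binary finger masks and Dice overlap by same / neighbour / non-neighbour finger pairs |
| `somatomap.glm` | blocked-design OLS GLM (double-gamma HRF + temporal derivatives + DCT high-pass), contrasts, percent signal change |
| `somatomap.rsa` | shrinkage noise normalisation, cross-validated squared Mahalanobis (crossnobis) RDMs, separability, typicality vs a canonical RDM, classical MDS with Procrustes alignment |
| `somatomap.stats` | Crawford–Howell single-case t-test, percentile bootstrap of group means, Benjamini–Hochberg FDR, Spearman covariate correlations, rank-based group tests, seeded permutation interaction test |
| `somatomap.pipeline` / `somatomap.cli` | orchestration, config, CSV/JSON/NIfTI IO, hashed run manifests |

## CLI

```bash
somatomap all --seed 1 --out results/full_run        # every stage
somatomap travelwave --config cfg.yaml --out results # through one stage
```

The configuration file is YAML/JSON with the fields of
`somatomap.pipeline.PipelineConfig` (cohort sizes, grid shape, noise level,
thresholds, shrinkage, bootstrap repetitions, global seed). Re-running with
the same config and seed reproduces every output; `manifest.json` records a
SHA-256 hash per output file.

```yaml
n_controls: 18
n_sci: 14
n_onehanders: 13
grid_shape: [20, 20, 10]
sigma: 0.5
seed: 1
out_dir: results/full_run
```

## Notes

- Autocorrelation-aware prewhitening of run-level GLMs is replaced by plain
  OLS (betas unbiased; variance estimates nominal). An AR(1)-style univariate
  alternative is available through the diagonal noise model in `rsa`.
- The canonical RDM defaults to a generator-derived noise-free reference;
  a user-supplied 5×5 CSV can be passed via `canonical_path` / `--config`.
- Robust trimmed-means ANOVA is substituted by a seeded permutation test on
  the same factorial structure.
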