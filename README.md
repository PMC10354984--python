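# methpanel

Analysis pipeline for a targeted DNA-methylation array panel comparing a
patient cohort against healthy controls, together with a fully seeded
synthetic-cohort simulator so every stage is testable offline.

Stages:

1. **simulate** — seeded generator for a probe manifest (gene panel with
   genomic positions, gene sections, SNP flags, control probes), a
   two-group sample sheet with realistic covariate marginals, a beta-value
   matrix with batch structure mirrored in control-probe intensities,
   detection p-values, and a height outcome at follow-up. Generation is on
   the M-value (logit2) scale so planted effects are additive where the
   models operate.
2. **preprocess** — sample QC (bimodality of the beta distribution,
   low-yield flags), probe QC (background detection, SNP overlap),
   beta↔M transforms, and batch-adjustment covariates as the leading
   principal components of the log2 control-probe intensities (negative
   controls excluded).
3. **dmp** — per-CpG moderated multivariable linear models on M-values
   (empirical-Bayes variance shrinkage across the panel), BH-FDR, and
   per-gene summaries.
4. **dmr** — Gaussian-kernel smoothing of squared per-site t-statistics,
   a two-moment (Satterthwaite) scaled chi-square null, BH across sites,
   and single-linkage chaining of significant sites at a ≤1000 bp gap.
   BED output.
5. **subgroups** — group×sex and group×(age ≥ 6 y at exposure)
   interaction contrasts at identified DMPs; glucocorticoid-treatment
   contrasts among patients, classified as aggravating or attenuating.
6. **height** — per-DMP multivariable models for height at follow-up
   with a robustness procedure: 100 iterations of 10-fold
   cross-validation, per-iteration Fisher combination of the 10
   test-fold p-values, robustness at ≥50% significant iterations, and a
   Harm/Benefit direction label.

## CLI

```sh
methpanel simulate   --config config.yaml --out data/ --seed 1
methpanel preprocess --in data/ --out clean/ [--k-pcs 30] [--det-p 0.01] [--fail-frac 0.01] [--mid-thresh 0.35]
methpanel dmp        --config config.yaml --in data/ --out run/ [--fdr 0.05]
methpanel dmr        --config config.yaml --out run/ [--lambda 1000] [--min-cpgs 2]
methpanel subgroups  --config config.yaml --out run/
methpanel height     --config config.yaml --out run/ [--iterations 100] [--folds 10]
methpanel all        --config config.yaml --out run/ --seed 1
```

`--config` is a YAML file with the fields of
`methpanel.pipeline.PipelineConfig` (seeds, QC thresholds, number of
control-probe PCs, FDR threshold, kernel bandwidth/scale, grouping gap,
age cutoff, CV settings, covariate lists, and a `simulation:` block with
`methpanel.simulate.SimulationConfig` fields). Omitting `--config` runs
the defaults. Re-running with an identical config and seed reproduces
byte-identical output tables; every run writes `run_manifest.json` with
the settings and versions used. Exit code 2 marks configuration errors,
1 a stage failure.

Example config:

```yaml
seed: 1
k_pcs: 10
fdr_threshold: 0.05
n_iterations: 100
simulation:
  n_patients: 818
  n_healthy: 392
  planted_dmps: {cg00000005: -0.5}
  height_coefficients: {cg00000005: 3.0}
```

## Layout

```
src/methpanel/
  simulate.py     synthetic manifests, cohorts, methylation, heights
  preprocess.py   QC, beta<->M, control-probe PCs
  stats.py        OLS, EB variance moderation, moderated t, BH, Fisher
  dmp.py          design matrices, DMP identification, gene summaries
  dmr.py          kernel smoothing, Satterthwaite null, region grouping
  subgroups.py    interaction and glucocorticoid contrasts
  height.py       height models and CV-Fisher robustness
  pipeline.py     end-to-end orchestration from a config
  reporting.py    publication-style table rendering
  cli.py          click command group
  io.py           delimited readers/writers
  datatypes.py    shared containers and record types
```
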