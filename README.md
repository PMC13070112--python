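# petcohort

Reference-tissue PET kinetic quantification, composite scoring and cohort
statistics, exercised end to end on synthetic cohorts.

The package implements the full analysis chain of a two-tracer PET/MRI
cognitive-aging design:

- **`petcohort.curves`** — frame schedules (26-frame and 18-frame 55-min
  dynamic protocols) and framewise time-activity curves (TACs).
- **`petcohort.kinetics`** — the multilinear reference tissue model (MRTM)
  for reversible ligands (`BP_ND = -β₁/β₂ - 1`) and a reference-Patlak fit
  for irreversible ligands with the exponential reference adjustment
  `C_ref(t) = C_cer(t)·e^(-0.04t)` over frames 4–26 (`Ki_ref` = slope);
  plus isotope-decay utilities.
- **`petcohort.synthetic`** — a seeded cohort generator: seven correlated
  latent constructs (age, sex, BMI, transporter availability, astrocyte
  marker, log lesion volume, cognition) with a calibrated correlation
  matrix, per-region kinetic ground truths, log-normal lesion volumes, a
  nine-test cognitive battery, and forward-simulated TACs for both tracers
  (SRTM convolution on a 0.1-min grid; frame-weighted Gaussian noise).
- **`petcohort.composites`** — z-scoring, the two-region striatal
  composite, the first-principal-component factor score over three
  regions, speed scores (correct responses/min) and domain/general
  cognition composites with the missing-test rules.
- **`petcohort.stats`** — ±3.29-SD univariate and Mahalanobis outlier
  rules, lesion log-transform, zero-order/partial Pearson correlations,
  hierarchical regression with standardized β, partial r and ΔR² F-tests,
  t/ANCOVA/chi-square group comparisons, Bonferroni adjustment, and exact
  noncentral-F power analysis (minimum N).
- **`petcohort.io` / `petcohort.cli`** — TSV/CSV formats with JSON
  sidecars and the pipeline driver.

## CLI

```sh
petcohort run --seed 1 --out out/                # simulate→fit→score→analyze
petcohort simulate --seed 1 --out out/           # cohort.csv + tacs/*.tsv
petcohort fit --tacs out/tacs --out out/fits.csv
petcohort score --cohort out/cohort.csv --fits out/fits.csv --out out/scored.csv
petcohort analyze --scored out/scored.csv --out out/results.csv
petcohort power --f2 0.15 --alpha 0.05 --power 0.8 --tested 1 --covariates 1
```

All subcommands accept `--config config.yaml` (keys: `seed`, `cohort`
overrides such as `n_subjects`/`noise_scale`, `patlak.lambda_bar`,
`patlak.fit_frames`, `models` with ordered predictor blocks). Every stage
writes a JSON sidecar with the seed, package version and input hashes;
runs are byte-identical under a fixed seed.

TAC bundles are TSV with columns `frame_start_s`, `frame_dur_s`, then one
activity column per region; the reference region column is named
`cerebellum`.

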