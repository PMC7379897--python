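# dyadphys

Autonomic-physiology analysis pipeline for dyadic target-tracking
experiments: extracts 23 autonomic parameters (15 HRV, 4 respiration, 4
EDA) per subject-trial, preprocesses subjective performance ratings, and
asks whether a quadratic-discriminant classifier predicts those ratings
better from the aggregated autonomic parameters or from the objective
tracking error.  A fully seeded synthetic cohort generator emulates the
experiment's structure (14 dyads, 2 recording days, 7 trials per condition
per day, 120-s trials, ratings on a 1-9 scale) so every stage is testable
without any recorded data.

## Package layout

| module                | contents |
|-----------------------|----------|
| `dyadphys.synthetic`  | `CohortConfig`, seeded generators for R-peak series, EDA traces, tracking traces, ratings, and whole cohorts |
| `dyadphys.hrv`        | `NNSeries`, time-domain / Poincaré / AR-spectral (Burg) HRV parameters |
| `dyadphys.resp_eda`   | breathing-rate extraction, respiration band powers, Bateman-kernel EDA decomposition, windowed SCL/SCR integrals |
| `dyadphys.behavior`   | tracking errors, rating outlier correction and level selection, pooled min-max-normalised `LabeledDataset` |
| `dyadphys.qda`        | from-scratch QDA, macro precision/recall/F1, leave-one-sample-out and leave-one-subject-out cross-validation |
| `dyadphys.selection`  | backward feature selection, N(N-1) permutation importance, label-permutation test, Benjamini-Hochberg FDR |
| `dyadphys.stats`      | Pearson correlation records, Wilcoxon signed-rank (exact + approximate), paired t-test |
| `dyadphys.pipeline`   | feature table assembly and the 16-cell scoring grid (4 rating/condition cells x 2 predictors x 2 CV schemes) |
| `dyadphys.cli` / `io` | command-line interface and plain-text cohort serialisation |

## CLI

```bash
dyadphys simulate --seed 1 --out cohort/          # write a synthetic cohort
dyadphys features --cohort cohort/ --out results/ # 23 parameters per trial
dyadphys classify --seed 1 --out results/         # 16 score rows
dyadphys all --seed 1 --n-perm 99 --out results/  # full pipeline + report
```

A YAML/JSON config (`--config run.yaml`) may override any cohort field
(`n_dyads`, `coupling_autonomic`, `coupling_error`,
`subject_heterogeneity`, ...) and run-level options (`cells`, `n_perm`).
Identical config + seed reproduces byte-identical outputs.

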