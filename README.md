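# immunodyn

Analysis pipeline for cell-type-resolved immune-feature dynamics in
two-timepoint, two-condition mass-cytometry cohorts, with a
ground-truthed synthetic-cohort generator so every stage is testable
without any external data.

The pipeline:

1. **Feature extraction** — converts labeled single-cell event tables
   into three feature categories per sample: subset frequencies (percent
   of labeled cells), basal signaling (mean arcsinh-transformed marker
   intensity per subset), and stimulation responses (difference of mean
   transformed intensities, stimulated minus unstimulated), with a
   configurable exclusion mask. The default panel has 21 subsets and 11
   functional markers (21 + 231 + 231 = 483 features with an empty mask).
2. **Dynamics** — per-patient rate of change
   `rho = (value_T2 - value_T1) / (GA_T2 - GA_T1)` in feature units per
   gestational week.
3. **Predictive model** — L1-penalized logistic regression on
   standardized rates (coordinate-descent solver with unpenalized
   intercept; penalty selected by inner cross-validation over a
   log-spaced path, one-standard-error rule by default), validated by
   repeated random holdout: train on all but 3 patients, predict the
   held-out 3, repeat 100 times; each patient's final blinded prediction
   is the mean of their out-of-sample probabilities, with a
   balanced-prior intercept correction that removes the training-
   prevalence leak unstratified holdout otherwise introduces. Reports
   ensemble AUC and a two-sided rank-sum p-value.
4. **Model reduction** — features ranked by selection frequency across
   holdout iterations; the ranking is cut at a two-segment
   piecewise-regression breakpoint to yield the informative set.
5. **Correlation network** — Spearman correlations between feature pairs
   (two-sided t-approximation p-values), edges at p < 1e-12 with weight
   −log10(p) (clamped at 300), Louvain communities, cosmetic t-SNE layout.
6. **Univariate statistics** — Shapiro-gated t-test / Mann-Whitney group
   comparisons with per-feature AUC, Fisher exact tests for binary
   covariates, and per-feature multiple-linear-regression confounder
   analysis (case status + BMI, autoimmune disease, chronic hypertension,
   type 2 diabetes).
7. **Synthetic cohorts** — feature-level and event-level generators with
   planted group-differential slopes, latent-factor correlation
   communities, and a serialized truth table.

## CLI

```bash
# synthetic cohort with 8 planted discriminative features
immunodyn simulate --out runs/sim --seed 17 --n-planted 8

# rates, model, reduction
immunodyn rates --t1 runs/sim/features_t1.csv --t2 runs/sim/features_t2.csv \
    --sheet runs/sim/sample_sheet.csv --out runs/sim/rates.csv
immunodyn fit --rates runs/sim/rates.csv --sheet runs/sim/sample_sheet.csv \
    --iters 100 --seed 17 --out runs/sim/model.json
immunodyn reduce --model runs/sim/model.json --out runs/sim/profile.csv

# network + univariate statistics
immunodyn network --t1 runs/sim/features_t1.csv --t2 runs/sim/features_t2.csv \
    --seed 17 --out runs/sim/network
immunodyn stats --rates runs/sim/rates.csv --sheet runs/sim/sample_sheet.csv \
    --out runs/sim/stats

# or everything from a YAML config
immunodyn run-all --config config.yaml
```

Minimal `config.yaml`:

```yaml
seed: 17
output_dir: runs/demo
simulate:
  n_planted: 8
  noise_sd: 0.1
model:
  n_iterations: 100
network:
  threshold: 1.0e-12
```

Real data enter through `inputs:` instead of `simulate:`: a directory of
per-sample event CSVs (columns: patient, timepoint, condition, cell_type,
one column per marker) plus a sample sheet CSV (patient, group ∈
{control, case}, GA_T1, GA_T2, optional covariates).

## Acceptance

The acceptance criteria are property-based (solver-vs-brute-force
equivalence, null-model calibration, planted-feature recovery, breakpoint
and AUC identities, community recovery, feature bookkeeping, rate
contracts, extraction round-trip) and live in `tests/test_acceptance.py`.
The report script runs a deterministic end-to-end self-check and writes
the (empty) numeric-target report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
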