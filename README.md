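# gosepred

Full-scale (8-level) Glasgow Outcome Scale Extended (GOSE) prediction after
traumatic brain injury, from the four classic admission variables: age,
GCS-motor score, pupillary reaction, and Marshall CT class.

The package provides, as tested library code plus a CLI:

- **Cohort I/O** (`gosepred.cohort`): a fixed CSV schema
  (`patient_id,age,gcs_motor,pupils,marshall,gose`), validation,
  complete-case filtering, and dummy-coded design matrices with optional
  training-partition age standardization.
- **Synthetic cohorts** (`gosepred.synthetic`): a generator with
  configurable covariate marginals, an optional shared latent severity
  coupling (Gaussian copula), and GOSE drawn from a proportional-odds law
  `P(Y <= j | x) = logistic(zeta_j - x.beta)`. Three built-in profiles
  (`uppsala`, `leuven`, `protect`) reproduce documented cohort
  compositions; their cutpoints are calibrated numerically so the marginal
  GOSE distribution hits the documented category fractions. A Monte-Carlo
  `bayes_accuracy` gives the argmax-oracle ceiling.
- **Proportional-odds logistic regression** (`gosepred.polr`): from-scratch
  likelihood, analytic gradient, L-BFGS-B fit on a strictly-increasing
  cutpoint reparameterization, no regularization, and the Brant (1990)
  test of the parallel-regression assumption (omnibus and per-variable
  Wald statistics).
- **Predictor contract** (`gosepred.predictors`): POLR, random forest
  (mtry=1, 500 trees, Gini), neural network (1600/800/200/100 ReLU layers,
  softmax output, batch 64, 24 epochs; scikit-learn backend), and
  majority-class / uniform-random baselines, all exposing `(n, 8)`
  probability matrices. Argmax ties break toward the lower (worse) GOSE.
- **Metric suite** (`gosepred.metrics`): accuracy, AW1/AW2, average
  balanced accuracy, macro precision/recall/specificity, mean and
  standard-deviation discrepancy (MD/SDD), predicted/observed category
  proportions with total and maximum discrepancies (TCPD/MCPD),
  dichotomized AUROC (mortality GOSE 1; unfavorable GOSE 1–4) via the
  midrank Mann–Whitney formulation, 8×8 confusion matrices, error
  distributions, and quantile-binned calibration curves.
- **Balanced-undersampling ensemble** (`gosepred.ensemble`): per-class
  undersampled subsamples, independent POLR members, median probability
  aggregation with renormalization.
- **Experiments** (`gosepred.experiments`): GOSE-stratified train/test
  split, stratified k-fold cross-validation, and training-size vs
  accuracy curves against a fixed simulated test cohort.
- **Figures** (`gosepred.figures`): confusion heat map, category
  proportion bars, error histograms, calibration panels with 2-SE bands.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the heavier end-to-end checks (Brant
type-I error over 500 replicates, the 20-replicate ensemble experiment,
sample-size curves against the Bayes ceiling); the whole suite runs in a
few minutes on one CPU.

## CLI

```bash
gosepred simulate --profile uppsala --n 866 --seed 1 --out cohort.csv
gosepred split --cohort cohort.csv --test-fraction 0.2 --seed 1 \
    --train-out train.csv --test-out test.csv
gosepred fit --cohort train.csv --kind polr --out fit.json --brant
gosepred predict --cohort test.csv --model fit.json --out preds.csv
gosepred evaluate --predictions preds.csv --out-json report.json \
    --out-tsv report.tsv --figures figs/
gosepred ensemble --cohort train.csv --members 200 --per-class 40 \
    --seed 1 --outdir ens/
gosepred cv --cohort train.csv --kind polr --folds 10 --seed 1 --out cv.json
gosepred samplesize --profile uppsala --sizes 100,200,400,800 \
    --replicates 10 --seed 1 --out curve.tsv
gosepred run-study --config study.yaml
```

A minimal `study.yaml`:

```yaml
output_dir: study_out
seed: 1
generator: {profile: uppsala, n: 866}
predictors: [polr, random_forest]
test_fraction: 0.2
figures: true
```

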