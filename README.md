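# nirauth

Chemometrics pipeline for NIR-based authentication of a high-value
botanical powder against adulteration: one-class authenticity decisions
via data-driven SIMCA, adulterant-fraction quantification via PLS
regression with systematic preprocessing screening, and a calibrated
synthetic spectrum generator so the whole workflow is testable without
instrument data.

## What's inside

| Module | Purpose |
| --- | --- |
| `nirauth.synthetic` | Synthetic log(1/R) spectra on a 10,000–4,000 cm⁻¹ grid (1557 points): 6 pure classes, binary mixtures at 20–80 % mass fraction, batch jitter, multiplicative scatter, baseline drift, additive noise; CSV I/O |
| `nirauth.preprocess` | SNV, MSC, Savitzky–Golay smoothing/derivatives, finite-difference derivatives, and the registry of 15 named screening pipelines (`RAW` … `SNV + 2nd Der + SG`) |
| `nirauth.sampling` | Kennard–Stone maximin selection; 6:2:2 (train/validation/test) and 7:3 (calibration/prediction) deterministic splits, optionally class-stratified |
| `nirauth.latent` | PCA, PLS-DA and OPLS-DA (NIPALS) with 7-fold cross-validated Q² |
| `nirauth.ddsimca` | One-class classifier: score/orthogonal distances, moment-based chi-squared degrees of freedom, acceptance and outlier thresholds, PC-count selection on the validation set |
| `nirauth.plsr` | PLS1 regression, latent-variable selection by 10-fold RMSECV, RMSE/R²/MAE/RPD metrics, per-adulterant preprocessing screen |
| `nirauth.classify` | DT / SVM / ANN / NB baselines (scikit-learn estimators) with stratified CV and hold-out confusion reports |
| `nirauth.cli` | `nirauth` command-line front end and the full-study orchestrator |

## CLI quick start

```bash
nirauth simulate --seed 42 --out dataset.csv
nirauth split --data dataset.csv --scheme 6:2:2 --out split.csv
nirauth preprocess --data dataset.csv --pipeline "SNV + 1st Der + SG" --out snv1d.csv
nirauth ddsimca --data dataset.csv --out ddsimca/
nirauth plsr --data dataset.csv --pair corn --seed 42 --out corn_screen.csv
nirauth classify --data dataset.csv --model svm --folds 10 --out classify/
nirauth run --seed 42 --out study/          # everything + manifest.json
```

`nirauth run` writes the dataset, split indices, the fitted one-class
model (JSON), per-subset decisions with acceptance-plot coordinates,
per-adulterant screening grids, classifier confusion matrices and a flat
`manifest.json` of headline metrics. Re-running with the same config is
byte-identical.

## Reproducibility notes

- One root seed drives everything; per-stage child streams are derived
  with `numpy.random.SeedSequence(seed, spawn_key=(k,))` (0 endmembers,
  1 batch jitter, 2 sample assembly).
- Preprocessing state (the MSC reference) is always fitted on
  calibration rows only; latent-variable and PC counts never see the
  test subset.
- Savitzky–Golay defaults are window 15, polynomial order 2; both are
  configurable everywhere they appear.
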