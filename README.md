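# chemprofiler

Chemical bioprofiling, assay-relevance ranking, structure curation and QSAR
modeling on sparse chemical–bioassay outcome tables.

Public screening repositories report, per compound and assay, a five-state
outcome (*active*, *probe*, *inactive*, *inconclusive*, *unspecified*), with
structures attached as InChI/InChIKey/SMILES. `chemprofiler` turns such
tables into biologically informed chemical descriptors and predictive
models, for computational toxicologists and cheminformaticians who want the
whole workflow scriptable and reproducible:

- **Bioprofiling.** Build a chemicals × assays matrix over {1, −1, 0}
  (active / inactive / unknown), keep assays with ≥ 1 active, rank assays by
  the mutual information between their binarized outcomes and each
  chemical's overall activity label (active in ≥ 1 assay), and fill the
  unknowns of the selected assays with per-assay random-forest classifiers
  trained on ECFP6 fingerprints (radius 3, 2048 bits; up to 500 actives and
  500 inactives sampled per assay, assays with < 100 compounds in either
  class rejected).
- **Assay relevance.** With per-assay active/inactive counts, rank assays by
  the Bayesian-smoothed active rate

      score_i = (Active_i + k·μ) / (Active_i + Inactive_i + k),
      μ = Σ Active_i / Σ (Active_i + Inactive_i),  k = 100,

  which shrinks small-sample hit rates toward the pooled rate μ; the top
  500 assays are reported.
- **Curation.** ChEMBL-style structure standardization on RDKit
  (normalize, strip salts/solvents to the largest organic parent,
  neutralize), issue flagging (stereo, valence, bonds, undesirable
  fragments), and duplicate resolution by standardized InChIKey under
  highest / lowest / average / remove policies.
- **QSAR.** ECFP6 / FCFP6 / physicochemical descriptors × RF / SVM / k-NN,
  grid-searched with 5-fold cross-validation, 0.5 classification threshold,
  batch prediction with `<ModelName>_Prediction` columns, and a
  three-component PCA chemical-space embedding.
- **Synthetic worlds.** A seeded scaffold+substituent grammar generates
  valid structures and plants substructure→activity rules, so every
  pipeline is testable against ground truth without any downloads.

## Worked example

Generate a planted-rule dataset, train a model, and predict:

```bash
chemprofiler simulate qsar --n 400 --rule nitro --noise 0.05 --seed 1 --out tox.csv
chemprofiler qsar train --in tox.csv --task binary --scheme ecfp6 --algo rf \
    --seed 1 --out tox_rf.joblib
chemprofiler qsar predict --model tox_rf.joblib \
    --smiles "O=[N+]([O-])c1ccccc1,c1ccccc1" --out pred.csv
```

The training step prints the chosen hyperparameters:

```
trained tox_ecfp6_rf; best params {'model__max_depth': 20, 'model__n_estimators': 500}
```

and `pred.csv` contains (after the provenance header):

```
smiles,tox_ecfp6_rf_Prediction,tox_ecfp6_rf_Probability
O=[N+]([O-])c1ccccc1,1,0.9557602130278002
c1ccccc1,0,0.01774957227819702
```

Nitrobenzene matches the planted nitro rule and is predicted active
(probability 0.956 ≥ 0.5 → label 1); benzene does not and is predicted
inactive. `tox_rf.metrics.csv` holds the per-fold and mean ± sd CV metrics
(accuracy, precision, recall, F1, ROC-AUC, PR-AUC) for the model.

The same workflows are available as library calls (`chemprofiler.qsar`,
`.profiling`, `.relevance`, `.curation`, `.store`, `.synthetic`); see
`docs/methods.md` for the model details and design choices.

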