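# pkcascade

Two-stage machine-learning prediction of **human intravenous pharmacokinetic
parameters** from chemical structure, for use in early drug discovery
(compound prioritization, DMTA cycles) where no experimental PK data exists
yet. The package predicts five endpoints:

| endpoint | meaning | unit |
|---|---|---|
| VDss | steady-state volume of distribution | L/kg |
| CL | total plasma clearance | mL/min/kg |
| t½ | elimination half-life | h |
| fu | fraction unbound in plasma | – |
| MRT | mean residence time | h |

## Method

**Stage 1** trains nine Random-Forest regressors for rat/dog/monkey ×
VDss/CL/fu from 2048-bit Morgan fingerprints (radius 2) and 2D
physicochemical descriptors. **Stage 2** predicts these nine animal
endpoints for every human-dataset compound and concatenates them with the
structural blocks to train the human models — a fully *in silico*
cross-species cascade: no measured animal data is needed at prediction
time.

Model selection uses 5×-repeated 5-fold **nested cross-validation**: inner
4-fold grid search picks Random-Forest hyperparameters, the outer folds
estimate generalization, and the hyperparameters of the fold with the
lowest geometric mean fold error are refit on all data as the final model.
For a prediction fᵢ and observation yᵢ (natural scale):

    FE_i  = max(f_i / y_i, y_i / f_i)                 fold error, >= 1
    GMFE  = 10 ^ mean_i( |log10 (f_i / y_i)| )        geometric mean fold error
    ALB   = mean_i( log10 (f_i / y_i) )               signed log bias

together with 2-/3-/5-fold accuracy percentages, median fold error, median
bias, and RMSE / R² on the log10 scale (raw scale for fu).

Each prediction carries an **uncertainty estimate**: an RBF kernel-ridge
regressor maps the query's mean 5-nearest-neighbour Tanimoto similarity to
the training set onto an expected fold error, giving a prediction range
[pred/FE, pred×FE]; a similarity below 0.25 raises an applicability-domain
alert.

Curation of raw tables follows a fixed protocol: SMILES standardization
(sanitize, normalize, largest fragment, canonical tautomer, pH-7.4
protonation), per-endpoint median merging of duplicates, removal of
compounds heavier than mean + 1.5 SD of the dataset's exact molecular
weight, and a decadic log transform of all endpoints except fu.

A seeded synthetic-data generator (`pkcascade.synthetic`) produces
drug-like SMILES with PK values carrying a known cross-species correlation
structure and sparsity, so every stage is trainable and testable without
any external download.

## Worked example

```python
from pkcascade import curation
from pkcascade.animal import train_animal_models
from pkcascade.cv import CVConfig
from pkcascade.human import predict_human, train_all_combos
from pkcascade.synthetic import SyntheticPKSpec, generate

animal_raw, human_raw, _ = generate(
    SyntheticPKSpec(n_human=250, n_animal=180, n_overlap=100, seed=4,
                    animal_species_missing={"rat": 0.1, "dog": 0.2, "monkey": 0.3}))
animal_ds, _ = curation.curate_dataset(animal_raw, "animal", curation.ANIMAL_ENDPOINTS)
human_ds, _ = curation.curate_dataset(human_raw, "human", curation.HUMAN_ENDPOINTS)

config = CVConfig(n_repeats=1, n_outer_folds=5, n_inner_folds=3,
                  hyper_grid=[dict(n_estimators=100, max_depth=None,
                                   min_samples_leaf=3, max_features=0.3)],
                  base_seed=0)
animal_models = train_animal_models(animal_ds, config)
human_models = train_all_combos(human_ds, animal_models, config,
                                combos=(1, 7, 10), endpoints=("VDss", "CL"))
rows = predict_human(["CC(=O)Oc1ccccc1C(=O)O"], human_models)
```

This prints (via `examples/04_human_cascade.py`):

```
endpoint combo                   median R2  median GMFE
VDss     1 fingerprints               0.19         3.11
VDss     7 all blocks                 0.40         2.60
VDss     10 mean baseline            -0.04         3.47
CL       1 fingerprints               0.30         2.67
CL       7 all blocks                 0.41         2.60
CL       10 mean baseline            -0.03         3.62

  CC(=O)Oc1ccccc1C(=O)[O-]
    VDss     0.57 L/kg      range [0.21, 1.52] (FE 2.68, AD alert: False)
    CL      20.56 mL/min/kg range [6.10, 69.29] (FE 3.37, AD alert: False)
```

The all-blocks model (combo 7, the released configuration) beats
fingerprints alone on both endpoints, the mean baseline sits at R² ≈ 0,
and each prediction comes with its similarity-calibrated fold-error range.
Aspirin's predicted VDss of 0.57 L/kg means roughly 0.2–1.5 L/kg once the
estimated fold error is taken into account.

The `examples/` directory holds one short script per capability
(standardization/curation, feature selection, stage-1 models, the human
cascade, fold-error/AD estimation, chemical-space analysis). A thin CLI
mirrors the workflow:

```bash
pkcascade make-fixtures --out-dir fixtures --n-human 200 --n-animal 150 --n-overlap 80
pkcascade curate fixtures/human_raw.csv --species human --out-csv curated/human.csv
pkcascade train-animal curated/animal.csv --out-model models/animal.joblib --small-grid
pkcascade train-human curated/human.csv --animal-model models/animal.joblib \
    --out-model models/human.joblib --combos 1,7,10
pkcascade predict models/human.joblib --input-csv queries.csv --out-csv predictions.csv
```

## Layout

- `src/pkcascade/` — library: `standardize`, `curation`, `features`,
  `cv`, `metrics`, `animal`, `human`, `uncertainty`, `chemspace`,
  `synthetic`, `io`, `cli`
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite incl. end-to-end acceptance tests
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
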