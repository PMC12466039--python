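"""Stage 1: nested-CV training of the nine animal PK models.

Trains rat/dog/monkey x VDss/CL/fu Random-Forest models on a small
synthetic animal dataset and prints per-model cross-validated metrics,
then predicts the 9-column animal-PK feature block for new compounds.
"""

from pkcascade import curation
from pkcascade.animal import predict_animal_features, train_animal_models
from pkcascade.cv import CVConfig
from pkcascade.synthetic import SyntheticPKSpec, generate

animal_raw, _, _ = generate(
    SyntheticPKSpec(n_human=30, n_animal=200, n_overlap=10, seed=3,
                    animal_species_missing={"rat": 0.1, "dog": 0.2, "monkey": 0.3})
)
dataset, _ = curation.curate_dataset(animal_raw, "animal", curation.ANIMAL_ENDPOINTS)
print(f"animal dataset: {len(dataset)} compounds, "
      f"{100 * dataset.sparsity():.1f}% sparse")

config = CVConfig(
    n_repeats=1, n_outer_folds=5, n_inner_folds=3,
    hyper_grid=[dict(n_estimators=100, max_depth=None, min_samples_leaf=3,
                     max_features=0.3)],
    base_seed=0,
)
model_set = train_animal_models(dataset, config)
print(f"{'model':<12} {'R2':>6} {'RMSE':>6} {'GMFE':>6} {'2-fold%':>8}")
for ep, bundle in model_set.models.items():
    res = bundle.cv_result
    print(f"{ep:<12} {res.mean_metric('r2'):6.2f} {res.mean_metric('rmse'):6.2f} "
          f"{res.mean_metric('gmfe'):6.2f} {res.mean_metric('pct_within_2fold'):8.1f}")

block, names = predict_animal_features(["CCO", "c1ccc2[nH]ccc2c1"], model_set)
print("\npredicted animal-PK features (log10 VDss/CL, raw fu):")
for row, smi in zip(block, ["CCO", "indole"]):
    print(f"  {smi:8s} " + " ".join(f"{v:6.2f}" for v in row))
# GMFE near 2 and R2 near 0.3-0.5 are the expected regime for in vivo PK
# endpoints modeled from structure alone; these 9 columns become the
# cross-species feature block of the human models.
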