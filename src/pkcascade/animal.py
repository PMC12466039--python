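"""Stage 1: animal PK models (rat/dog/monkey × VDss/CL/fu).

Nine Random-Forest regressors are trained on the curated animal dataset from
Morgan fingerprints plus physicochemical descriptors, one per
(species, endpoint) pair, each through the shared nested-CV harness. Feature
selection and scaling are fit per species on the compounds annotated for that
species. The trained set then predicts all nine animal endpoints for
arbitrary compounds — these predictions are the cross-species feature block
of the stage-2 human models. VDss and CL are modeled and emitted on the
log10 scale (passed through as features without back-transform); fu is
modeled raw and clipped to [1e-4, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import ANIMAL_PK, ANIMAL_SPECIES, PKDataset, endpoint_scale
from .cv import CVConfig, ModelBundle, retrain_final, run_nested_cv, select_best_model
from .features import FeatureRecipe, apply_scaler, fit_scaler, morgan_fingerprint

FU_FLOOR = 1e-4

#: fixed column order of the predicted-animal-PK feature block
ANIMAL_FEATURE_ORDER = tuple(
    f"{species}_{endpoint}" for species in ANIMAL_SPECIES for endpoint in ANIMAL_PK
)

MIN_COMPOUNDS_PER_ENDPOINT = 25


@dataclass
class SpeciesRecipe:
    recipe: FeatureRecipe
    scaler_state: tuple[np.ndarray, np.ndarray]
    smiles: list[str]

    def features_for(self, std_smiles_list: list[str]) -> np.ndarray:
        fm = self.recipe.transform(std_smiles_list)
        return apply_scaler(fm, self.scaler_state).matrix


@dataclass
class AnimalModelSet:
    models: dict[str, ModelBundle] = field(default_factory=dict)  # "rat_VDss" → bundle
    recipes: dict[str, SpeciesRecipe] = field(default_factory=dict)  # species → recipe

    def __post_init__(self):
        pass

    @property
    def endpoints(self) -> tuple[str, ...]:
        return ANIMAL_FEATURE_ORDER


def train_animal_models(
    animal_dataset: PKDataset, config: CVConfig
) -> AnimalModelSet:
    """Train the 9 animal models via nested CV → best-fold params → retrain."""
    model_set = AnimalModelSet()
    for species in ANIMAL_SPECIES:
        species_eps = [f"{species}_{ep}" for ep in ANIMAL_PK]
        has_any = np.zeros(len(animal_dataset), dtype=bool)
        for ep in species_eps:
            has_any |= animal_dataset.annotated_mask(ep)
        smiles = [s for s, keep in zip(animal_dataset.std_smiles, has_any) if keep]
        if len(smiles) < MIN_COMPOUNDS_PER_ENDPOINT:
            raise ValueError(
                f"only {len(smiles)} compounds annotated for {species}; "
                f"need >= {MIN_COMPOUNDS_PER_ENDPOINT}"
            )
        recipe = FeatureRecipe().fit(smiles)
        fm = fit_scaler(recipe.transform(smiles))
        species_recipe = SpeciesRecipe(recipe, fm.scaler_state, smiles)
        model_set.recipes[species] = species_recipe

        keep_idx = np.flatnonzero(has_any)
        for ep in species_eps:
            mask_full = animal_dataset.annotated_mask(ep)
            y_full = animal_dataset.endpoint_values(ep)
            rows = [i for i, gi in enumerate(keep_idx) if mask_full[gi]]
            if len(rows) < MIN_COMPOUNDS_PER_ENDPOINT:
                raise ValueError(
                    f"endpoint {ep} has {len(rows)} annotated compounds; "
                    f"need >= {MIN_COMPOUNDS_PER_ENDPOINT}"
                )
            X = fm.matrix[rows]
            y = y_full[keep_idx[rows]]
            scale = endpoint_scale(ep)
            result = run_nested_cv(X, y, config, scale=scale, endpoint=ep)
            params = select_best_model(result)
            fps = [morgan_fingerprint(smiles[i]) for i in rows]
            bundle = retrain_final(
                X,
                y,
                params,
                seed=config.base_seed,
                endpoint=ep,
                scale=scale,
                feature_names=list(fm.feature_names),
                scaler_state=fm.scaler_state,
                train_fingerprints=fps,
                cv_result=result,
            )
            model_set.models[ep] = bundle
    return model_set


def predict_animal_features(
    std_smiles_list: list[str], model_set: AnimalModelSet
) -> tuple[np.ndarray, list[str]]:
    """Predicted animal PK block: compounds × 9, fixed column order.

    Log-scale VDss/CL predictions pass through untransformed; fu predictions
    are clipped to [FU_FLOOR, 1].
    """
    n = len(std_smiles_list)
    out = np.zeros((n, len(ANIMAL_FEATURE_ORDER)))
    features_cache: dict[str, np.ndarray] = {}
    for j, ep in enumerate(ANIMAL_FEATURE_ORDER):
        species = ep.split("_", 1)[0]
        if species not in features_cache:
            features_cache[species] = model_set.recipes[species].features_for(
                std_smiles_list
            )
        pred = model_set.models[ep].predict(features_cache[species])
        if endpoint_scale(ep) == "raw":
            pred = np.clip(pred, FU_FLOOR, 1.0)
        out[:, j] = pred
    return out, list(ANIMAL_FEATURE_ORDER)
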