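"""Stage 2: human PK models over ten feature-combination variants.

For each human endpoint (VDss, CL, t½, fu, MRT) ten model variants are
compared in the identical nested-CV harness with identical fold assignments,
so per-fold metrics are paired across variants:

1. Morgan fingerprints; 2. physicochemical descriptors; 3. predicted animal
PK; 4. 1+2; 5. 1+3; 6. 2+3; 7. 1+2+3; 8. animal PK, measured values
overwriting predictions where available; 9. 1+2+8; 10. a mean-predictor
baseline.

The released model is variant 7 (all three blocks) for every endpoint, each
paired with a similarity → fold-error regressor fit on that endpoint's own
CV fold errors. Predictions for new compounds are returned in natural units
(10**x for log endpoints, fu clipped to (0, 1]) with an estimated fold
error, a [pred/FE, pred×FE] range, and an applicability-domain alert when
5-NN Tanimoto similarity to the training set falls below 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .animal import ANIMAL_FEATURE_ORDER, FU_FLOOR, AnimalModelSet, predict_animal_features
from .curation import HUMAN_ENDPOINTS, PKDataset, endpoint_scale
from .cv import CVConfig, ModelBundle, retrain_final, run_nested_cv, select_best_model
from .features import FeatureMatrix, FeatureRecipe, apply_scaler, fit_scaler, morgan_fingerprint
from .standardize import SmilesParseError, standardize_smiles
from .uncertainty import (
    FoldErrorModel,
    collect_similarity_fe_pairs,
    estimate_fold_error,
    fit_fold_error_model,
)

#: feature blocks per combination id; "animal_mixed" = measured-where-available
COMBO_BLOCKS: dict[int, tuple[str, ...]] = {
    1: ("morgan",),
    2: ("physchem",),
    3: ("animal_pred",),
    4: ("morgan", "physchem"),
    5: ("morgan", "animal_pred"),
    6: ("physchem", "animal_pred"),
    7: ("morgan", "physchem", "animal_pred"),
    8: ("animal_mixed",),
    9: ("morgan", "physchem", "animal_mixed"),
    10: (),  # mean-predictor baseline
}

FINAL_COMBO = 7
BASELINE_COMBO = 10


@dataclass
class FeatureCombo:
    combo_id: int

    def __post_init__(self):
        if self.combo_id not in COMBO_BLOCKS:
            raise ValueError(f"unknown combo id {self.combo_id}")

    @property
    def blocks(self) -> tuple[str, ...]:
        return COMBO_BLOCKS[self.combo_id]

    @property
    def is_baseline(self) -> bool:
        return self.combo_id == BASELINE_COMBO


def build_blocks(
    human_dataset: PKDataset,
    animal_models: AnimalModelSet,
    real_animal: PKDataset | None = None,
) -> tuple[FeatureRecipe, dict[str, FeatureMatrix]]:
    """Compute all stage-2 feature blocks for the human dataset once."""
    smiles = human_dataset.std_smiles
    recipe = FeatureRecipe().fit(smiles)
    morgan, physchem = recipe.transform_blocks(smiles)
    animal_pred, animal_names = predict_animal_features(smiles, animal_models)
    blocks = {
        "morgan": morgan,
        "physchem": physchem,
        "animal_pred": FeatureMatrix("animal_pred", animal_pred, list(animal_names)),
    }
    mixed = animal_pred.copy()
    if real_animal is not None:
        by_smiles = {r.std_smiles: r for r in real_animal.records}
        for i, smi in enumerate(smiles):
            rec = by_smiles.get(smi)
            if rec is None:
                continue
            for j, ep in enumerate(ANIMAL_FEATURE_ORDER):
                if ep in rec.endpoints:
                    mixed[i, j] = rec.endpoints[ep]
    blocks["animal_mixed"] = FeatureMatrix(
        "animal_mixed", mixed, [f"mixed_{n}" for n in animal_names]
    )
    return recipe, blocks


def assemble_features(
    blocks: dict[str, FeatureMatrix], combo: FeatureCombo
) -> FeatureMatrix:
    """Concatenate the combo's blocks in fixed order (unscaled)."""
    if not combo.blocks:
        if combo.is_baseline:
            # the mean predictor ignores features; give it a constant column
            n = next(iter(blocks.values())).matrix.shape[0]
            return FeatureMatrix("baseline", np.zeros((n, 1)), ["const"])
        raise ValueError("no feature blocks selected")
    mats = [blocks[b].matrix for b in combo.blocks]
    names = [n for b in combo.blocks for n in blocks[b].feature_names]
    return FeatureMatrix("+".join(combo.blocks), np.hstack(mats), names)


@dataclass
class HumanModelSet:
    recipe: FeatureRecipe
    cv_results: dict[tuple[str, int], object] = field(default_factory=dict)
    bundles: dict[tuple[str, int], ModelBundle] = field(default_factory=dict)
    scalers: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    fe_models: dict[str, FoldErrorModel] = field(default_factory=dict)
    animal_models: AnimalModelSet | None = None
    final_combo: int = FINAL_COMBO

    def final_bundle(self, endpoint: str) -> ModelBundle:
        return self.bundles[(endpoint, self.final_combo)]


def train_all_combos(
    human_dataset: PKDataset,
    animal_models: AnimalModelSet,
    config: CVConfig,
    combos: tuple[int, ...] = tuple(COMBO_BLOCKS),
    endpoints: tuple[str, ...] = HUMAN_ENDPOINTS,
    real_animal: PKDataset | None = None,
    fit_fold_error: bool = True,
    min_fe_pairs: int = 20,
) -> HumanModelSet:
    """Nested CV + final retrain for every (endpoint, combo) pair.

    Fold assignments depend only on (endpoint sample count, config seed), so
    every combo sees identical folds per endpoint and comparisons are paired.
    """
    recipe, blocks = build_blocks(human_dataset, animal_models, real_animal)
    model_set = HumanModelSet(recipe=recipe, animal_models=animal_models)
    smiles = human_dataset.std_smiles
    fps = [morgan_fingerprint(s) for s in smiles]

    scaled: dict[int, FeatureMatrix] = {}
    for combo_id in combos:
        combo = FeatureCombo(combo_id)
        fm = assemble_features(blocks, combo)
        if combo.is_baseline:
            scaled[combo_id] = fm  # constant column; scaling is meaningless
            model_set.scalers[combo_id] = (
                np.zeros(fm.matrix.shape[1]),
                np.ones(fm.matrix.shape[1]),
            )
        else:
            sfm = fit_scaler(fm)
            scaled[combo_id] = sfm
            model_set.scalers[combo_id] = sfm.scaler_state

    for endpoint in endpoints:
        mask = human_dataset.annotated_mask(endpoint)
        rows = np.flatnonzero(mask)
        y = human_dataset.endpoint_values(endpoint)[rows]
        scale = endpoint_scale(endpoint)
        for combo_id in combos:
            combo = FeatureCombo(combo_id)
            X = scaled[combo_id].matrix[rows]
            cfg = CVConfig(
                n_repeats=config.n_repeats,
                n_outer_folds=config.n_outer_folds,
                n_inner_folds=config.n_inner_folds,
                hyper_grid=[{}] if combo.is_baseline else config.hyper_grid,
                base_seed=config.base_seed,
                estimator="mean" if combo.is_baseline else "rf",
                inner_scoring=config.inner_scoring,
            )
            result = run_nested_cv(X, y, cfg, scale=scale, endpoint=endpoint)
            params = select_best_model(result)
            bundle = retrain_final(
                X,
                y,
                params,
                seed=config.base_seed,
                endpoint=endpoint,
                scale=scale,
                feature_names=list(scaled[combo_id].feature_names),
                scaler_state=model_set.scalers[combo_id],
                train_fingerprints=[fps[i] for i in rows],
                estimator=cfg.estimator,
                cv_result=result,
            )
            model_set.cv_results[(endpoint, combo_id)] = result
            model_set.bundles[(endpoint, combo_id)] = bundle

        if fit_fold_error and FINAL_COMBO in combos:
            result = model_set.cv_results[(endpoint, FINAL_COMBO)]
            sub_fps = [fps[i] for i in rows]
            sims, fes = collect_similarity_fe_pairs(result, sub_fps, y)
            if len(sims) >= min_fe_pairs:
                model_set.fe_models[endpoint] = fit_fold_error_model(
                    sims,
                    fes,
                    train_fingerprints=sub_fps,
                    endpoint=endpoint,
                    seed=config.base_seed,
                )
    return model_set


def predict_human(
    smiles_list: list[str],
    model_set: HumanModelSet,
    endpoints: tuple[str, ...] | None = None,
) -> list[dict]:
    """Per-compound predictions in natural units with fold-error estimates.

    Invalid SMILES yield a row with an ``error`` entry; the batch continues.
    """
    if endpoints is None:
        endpoints = tuple(
            ep for (ep, c) in model_set.bundles if c == model_set.final_combo
        )
        endpoints = tuple(dict.fromkeys(endpoints))
    rows: list[dict] = []
    std_ok: list[str] = []
    idx_ok: list[int] = []
    for i, raw in enumerate(smiles_list):
        try:
            std = standardize_smiles(raw)
            std_ok.append(std)
            idx_ok.append(i)
            rows.append({"smiles": raw, "std_smiles": std})
        except SmilesParseError as exc:
            rows.append({"smiles": raw, "error": str(exc)})
    if not std_ok:
        return rows

    morgan, physchem = model_set.recipe.transform_blocks(std_ok)
    animal_pred, animal_names = predict_animal_features(
        std_ok, model_set.animal_models
    )
    blocks = {
        "morgan": morgan,
        "physchem": physchem,
        "animal_pred": FeatureMatrix("animal_pred", animal_pred, list(animal_names)),
    }
    combo = FeatureCombo(model_set.final_combo)
    fm = assemble_features(blocks, combo)
    X = apply_scaler(fm, model_set.scalers[model_set.final_combo]).matrix

    ok_rows = [rows[i] for i in range(len(rows)) if "error" not in rows[i]]
    for endpoint in endpoints:
        bundle = model_set.bundles[(endpoint, model_set.final_combo)]
        pred = bundle.predict(X)
        if endpoint_scale(endpoint) == "log10":
            natural = 10.0 ** pred
        else:
            natural = np.clip(pred, FU_FLOOR, 1.0)
        fe_model = model_set.fe_models.get(endpoint)
        for j, row in enumerate(ok_rows):
            entry = {"prediction": float(natural[j])}
            if fe_model is not None:
                fe, sim, alert = estimate_fold_error(row["std_smiles"], fe_model)
                entry.update(
                    fold_error=fe,
                    range_low=float(natural[j] / fe),
                    range_high=float(natural[j] * fe),
                    similarity_5nn=sim,
                    ad_alert=bool(alert),
                )
            row[endpoint] = entry
    return rows
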