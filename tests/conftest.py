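"""Shared fixtures: one small synthetic study, curated and modeled once.

The synthetic datasets are deliberately small (a few hundred compounds, one
CV repeat, a single hyperparameter candidate) so the whole suite runs in
minutes; the study-condition defaults of the generator are exercised in the
acceptance tests at larger sizes.
"""

import numpy as np
import pytest

from pkcascade import curation, cv
from pkcascade.animal import train_animal_models
from pkcascade.human import train_all_combos
from pkcascade.synthetic import SyntheticPKSpec, generate

SEED = 11


@pytest.fixture(scope="session")
def raw_tables():
    spec = SyntheticPKSpec(
        n_human=220,
        n_animal=180,
        n_overlap=100,
        n_external=160,
        seed=SEED,
        animal_species_missing={"rat": 0.10, "dog": 0.20, "monkey": 0.30},
    )
    animal_raw, human_raw, truth = generate(spec)
    return animal_raw, human_raw, truth, spec


@pytest.fixture(scope="session")
def animal_ds(raw_tables):
    animal_raw, _, _, _ = raw_tables
    ds, report = curation.curate_dataset(animal_raw, "animal", curation.ANIMAL_ENDPOINTS)
    return ds


@pytest.fixture(scope="session")
def human_ds(raw_tables):
    _, human_raw, _, _ = raw_tables
    ds, report = curation.curate_dataset(human_raw, "human", curation.HUMAN_ENDPOINTS)
    return ds


@pytest.fixture(scope="session")
def fast_cfg():
    # single candidate: the inner grid search short-circuits
    return cv.CVConfig(
        n_repeats=1,
        n_outer_folds=5,
        n_inner_folds=3,
        hyper_grid=[
            dict(n_estimators=100, max_depth=None, min_samples_leaf=3, max_features=0.3)
        ],
        base_seed=SEED,
    )


@pytest.fixture(scope="session")
def animal_models(animal_ds, fast_cfg):
    return train_animal_models(animal_ds, fast_cfg)


@pytest.fixture(scope="session")
def human_models(human_ds, animal_ds, animal_models, fast_cfg):
    return train_all_combos(
        human_ds,
        animal_models,
        fast_cfg,
        combos=(1, 4, 7, 8, 10),
        endpoints=("VDss", "CL", "fu"),
        real_animal=animal_ds,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
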