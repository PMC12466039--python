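"""Nested-CV harness: partitioning, determinism, leakage, model selection."""

import numpy as np
import pytest

from pkcascade.cv import (
    CVConfig,
    FoldResult,
    NestedCVResult,
    retrain_final,
    run_nested_cv,
    select_best_model,
)
from pkcascade.metrics import evaluate


def make_linear_data(rng, n=50, p=6, noise=0.3):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


@pytest.fixture(scope="module")
def quick_cfg():
    return CVConfig(
        n_repeats=2,
        n_outer_folds=5,
        n_inner_folds=3,
        hyper_grid=[dict(n_estimators=50, max_depth=None, min_samples_leaf=2, max_features=0.5)],
        base_seed=3,
    )


def test_every_compound_held_out_once_per_repeat(rng, quick_cfg):
    X, y = make_linear_data(rng)
    result = run_nested_cv(X, y, quick_cfg)
    assert len(result.folds) == quick_cfg.n_folds_total
    for repeat in range(quick_cfg.n_repeats):
        test_ids = np.concatenate(
            [f.test_idx for f in result.folds if f.repeat == repeat]
        )
        assert sorted(test_ids) == list(range(len(y)))


def test_no_train_test_leakage(rng, quick_cfg):
    X, y = make_linear_data(rng)
    result = run_nested_cv(X, y, quick_cfg)
    for fold in result.folds:
        assert len(np.intersect1d(fold.train_idx, fold.test_idx)) == 0
        assert len(fold.train_idx) + len(fold.test_idx) == len(y)


def test_same_seed_identical_results(rng, quick_cfg):
    X, y = make_linear_data(rng)
    r1 = run_nested_cv(X, y, quick_cfg)
    r2 = run_nested_cv(X, y, quick_cfg)
    for f1, f2 in zip(r1.folds, r2.folds):
        np.testing.assert_array_equal(f1.test_idx, f2.test_idx)
        np.testing.assert_array_equal(f1.y_pred, f2.y_pred)


def test_different_seed_different_folds(rng):
    X, y = make_linear_data(rng)
    cfgs = [
        CVConfig(n_repeats=1, hyper_grid=[dict(n_estimators=20)], base_seed=s)
        for s in (1, 2)
    ]
    r1, r2 = (run_nested_cv(X, y, c) for c in cfgs)
    assert any(
        not np.array_equal(f1.test_idx, f2.test_idx)
        for f1, f2 in zip(r1.folds, r2.folds)
    )


def test_grid_search_selects_among_candidates(rng):
    X, y = make_linear_data(rng, n=60)
    grid = [
        dict(n_estimators=30, max_depth=2, min_samples_leaf=1, max_features=1.0),
        dict(n_estimators=60, max_depth=None, min_samples_leaf=1, max_features=1.0),
    ]
    cfg = CVConfig(n_repeats=1, n_inner_folds=3, hyper_grid=grid, base_seed=5)
    result = run_nested_cv(X, y, cfg)
    assert all(f.params in grid for f in result.folds)


def test_too_few_samples_errors(quick_cfg):
    with pytest.raises(ValueError):
        run_nested_cv(np.zeros((3, 2)), np.zeros(3), quick_cfg)


def test_pure_noise_r2_not_positive(rng):
    cfg = CVConfig(n_repeats=1, hyper_grid=[dict(n_estimators=30)], base_seed=0)
    medians = []
    for rep in range(10):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        result = run_nested_cv(X, y, cfg)
        medians.append(result.median_metric("r2"))
    assert np.median(medians) < 0.05


class TestSelection:
    @staticmethod
    def fold(gmfe_value, n_estimators=100, max_depth=None, order=0):
        y = np.array([0.0, 0.0])
        pred = np.array([np.log10(gmfe_value)] * 2)
        return FoldResult(
            repeat=0,
            fold=order,
            train_idx=np.array([0]),
            test_idx=np.array([1]),
            params=dict(n_estimators=n_estimators, max_depth=max_depth),
            y_pred=pred,
            metrics=evaluate(y, pred),
        )

    def test_argmin_gmfe(self):
        folds = [self.fold(2.0), self.fold(1.5, n_estimators=200), self.fold(3.0)]
        result = NestedCVResult(folds, "log10", "CL")
        assert select_best_model(result)["n_estimators"] == 200

    def test_tie_break_prefers_simpler(self):
        folds = [
            self.fold(2.0, n_estimators=500, max_depth=None, order=0),
            self.fold(2.0, n_estimators=100, max_depth=None, order=1),
            self.fold(2.0, n_estimators=100, max_depth=8, order=2),
        ]
        result = NestedCVResult(folds, "log10", "CL")
        best = select_best_model(result)
        assert best["n_estimators"] == 100 and best["max_depth"] == 8

    def test_perfect_fold_always_selected(self):
        folds = [self.fold(2.0), self.fold(1.0, n_estimators=250), self.fold(1.4)]
        result = NestedCVResult(folds, "log10", "CL")
        assert select_best_model(result)["n_estimators"] == 250


class TestRetrain:
    def test_in_sample_gmfe_not_worse_than_cv(self, rng, quick_cfg):
        X, y = make_linear_data(rng, n=60)
        result = run_nested_cv(X, y, quick_cfg)
        params = select_best_model(result)
        bundle = retrain_final(X, y, params, seed=3)
        in_sample = evaluate(y, bundle.predict(X)).gmfe
        assert in_sample <= result.median_metric("gmfe")

    def test_rf_predictions_bounded_by_training_targets(self, rng):
        X, y = make_linear_data(rng, n=60)
        bundle = retrain_final(X, y, dict(n_estimators=30), seed=1)
        pred = bundle.predict(rng.normal(size=(20, X.shape[1])) * 5)
        assert pred.min() >= y.min() and pred.max() <= y.max()

    def test_serialization_round_trip_bit_identical(self, rng, tmp_path):
        from pkcascade.io import load_bundle, save_bundle

        X, y = make_linear_data(rng, n=40)
        bundle = retrain_final(X, y, dict(n_estimators=20), seed=1)
        save_bundle(bundle, tmp_path / "m.joblib")
        loaded = load_bundle(tmp_path / "m.joblib")
        Xq = rng.normal(size=(10, X.shape[1]))
        np.testing.assert_array_equal(bundle.predict(Xq), loaded.predict(Xq))

    def test_schema_mismatch_errors(self, rng):
        X, y = make_linear_data(rng, n=30)
        bundle = retrain_final(X, y, dict(n_estimators=10), seed=1)
        with pytest.raises(ValueError, match="schema"):
            bundle.predict(np.zeros((2, X.shape[1] + 1)))


def test_mean_baseline_heldout_r2_not_positive(rng):
    cfg = CVConfig(
        n_repeats=2, hyper_grid=[{}], base_seed=4, estimator="mean"
    )
    X, y = make_linear_data(rng, n=50)
    result = run_nested_cv(X, y, cfg)
    assert result.median_metric("r2") <= 0
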