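"""Repeated nested cross-validation with GMFE-based model selection.

The harness shared by the animal-PK (stage 1) and human-PK (stage 2) models:
``n_repeats`` × ``n_outer_folds`` outer evaluation folds (25 by default);
within each outer training portion, a grid search over Random-Forest
hyperparameters scored by ``n_inner_folds``-fold CV minimizing natural-scale
GMFE; the winning configuration predicts the held-out fold. The fold with the
lowest outer GMFE supplies the hyperparameters for the final model, retrained
on all data.

Fold assignments are a pure function of (n samples, config, base_seed) and of
nothing else, so different feature combinations evaluated on the same
endpoint share identical folds and their fold metrics are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .metrics import MetricsReport, evaluate

_SEED_MOD = 2**31 - 1


def default_rf_grid() -> list[dict]:
    """Default Random-Forest hyperparameter grid (fully configurable)."""
    grid = []
    for n_estimators in (100, 250, 500):
        for max_depth in (8, 12, None):
            for min_samples_leaf in (1, 3, 5):
                for max_features in ("sqrt", 0.3):
                    grid.append(
                        dict(
                            n_estimators=n_estimators,
                            max_depth=max_depth,
                            min_samples_leaf=min_samples_leaf,
                            max_features=max_features,
                        )
                    )
    return grid


def small_rf_grid() -> list[dict]:
    """Reduced grid for scaled-down runs: tree count fixed, depth varied."""
    return [
        dict(n_estimators=100, max_depth=None, min_samples_leaf=3, max_features="sqrt"),
        dict(n_estimators=100, max_depth=8, min_samples_leaf=3, max_features="sqrt"),
    ]


@dataclass
class CVConfig:
    n_repeats: int = 5
    n_outer_folds: int = 5
    n_inner_folds: int = 4
    hyper_grid: list[dict] = field(default_factory=default_rf_grid)
    base_seed: int = 0
    estimator: str = "rf"  # "rf" or "mean" (baseline)
    inner_scoring: str = "gmfe"  # or "rmse"

    @property
    def n_folds_total(self) -> int:
        return self.n_repeats * self.n_outer_folds


def make_estimator(params: dict, seed: int, kind: str = "rf"):
    if kind == "mean":
        return DummyRegressor(strategy="mean")
    return RandomForestRegressor(random_state=seed, n_jobs=1, **params)


@dataclass
class FoldResult:
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    params: dict
    y_pred: np.ndarray
    metrics: MetricsReport


@dataclass
class NestedCVResult:
    folds: list[FoldResult]
    scale: str
    endpoint: str

    def fold_metric(self, name: str) -> np.ndarray:
        return np.array([getattr(f.metrics, name) for f in self.folds])

    def median_metric(self, name: str) -> float:
        return float(np.median(self.fold_metric(name)))

    def mean_metric(self, name: str) -> float:
        return float(np.mean(self.fold_metric(name)))

    @property
    def best_fold(self) -> FoldResult:
        return select_best_fold(self)


def _fold_seed(base_seed: int, repeat: int, fold: int = 0, salt: int = 0) -> int:
    return (base_seed * 1_000_003 + repeat * 7_919 + fold * 104_729 + salt) % _SEED_MOD


def _score_candidate(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    config: CVConfig,
    scale: str,
    seed: int,
) -> float:
    """Inner-CV score for one hyperparameter candidate (lower is better)."""
    inner = KFold(n_splits=config.n_inner_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, va in inner.split(X):
        est = make_estimator(params, seed, config.estimator)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[va])
        rep = evaluate(y[va], pred, scale=scale)
        scores.append(rep.gmfe if config.inner_scoring == "gmfe" else rep.rmse)
    return float(np.mean(scores))


def run_nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    scale: str = "log10",
    endpoint: str = "",
) -> NestedCVResult:
    """Run the full repeated nested CV; returns all 25 fold prediction sets."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < config.n_outer_folds:
        raise ValueError(
            f"need at least {config.n_outer_folds} samples, got {len(y)}"
        )
    if np.all(y == y[0]):
        import warnings

        warnings.warn("constant target: R² is undefined and flagged in metrics")
    folds: list[FoldResult] = []
    for repeat in range(config.n_repeats):
        outer = KFold(
            n_splits=config.n_outer_folds,
            shuffle=True,
            random_state=_fold_seed(config.base_seed, repeat),
        )
        for fold, (train_idx, test_idx) in enumerate(outer.split(X)):
            seed = _fold_seed(config.base_seed, repeat, fold, salt=1)
            if len(config.hyper_grid) > 1 and config.estimator != "mean":
                scores = [
                    _score_candidate(
                        X[train_idx], y[train_idx], params, config, scale, seed
                    )
                    for params in config.hyper_grid
                ]
                best_params = config.hyper_grid[int(np.argmin(scores))]
            else:
                best_params = config.hyper_grid[0] if config.hyper_grid else {}
            est = make_estimator(best_params, seed, config.estimator)
            est.fit(X[train_idx], y[train_idx])
            y_pred = est.predict(X[test_idx])
            folds.append(
                FoldResult(
                    repeat=repeat,
                    fold=fold,
                    train_idx=train_idx,
                    test_idx=test_idx,
                    params=dict(best_params),
                    y_pred=y_pred,
                    metrics=evaluate(y[test_idx], y_pred, scale=scale, endpoint=endpoint),
                )
            )
    return NestedCVResult(folds=folds, scale=scale, endpoint=endpoint)


def _tie_key(fold: FoldResult, order: int):
    depth = fold.params.get("max_depth")
    return (
        fold.params.get("n_estimators", 0),
        np.inf if depth is None else depth,
        order,
    )


def select_best_fold(result: NestedCVResult) -> FoldResult:
    """Fold with the lowest GMFE; ties go to the simpler model, then fold order."""
    gmfes = result.fold_metric("gmfe")
    best = np.min(gmfes)
    candidates = [
        (i, f) for i, f in enumerate(result.folds) if result.folds[i].metrics.gmfe == best
    ]
    return min(candidates, key=lambda pair: _tie_key(pair[1], pair[0]))[1]


def select_best_model(result: NestedCVResult) -> dict:
    """Hyperparameters of the minimum-GMFE fold."""
    return dict(select_best_fold(result).params)


@dataclass
class ModelBundle:
    """A final retrained model with everything needed to predict new compounds."""

    model: object
    params: dict
    seed: int
    endpoint: str
    scale: str
    feature_names: list[str]
    scaler_state: tuple[np.ndarray, np.ndarray] | None
    train_fingerprints: list | None = None  # Morgan bit vectors for AD / FE
    y_train_range: tuple[float, float] | None = None
    cv_result: NestedCVResult | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature schema mismatch: expected {len(self.feature_names)} "
                f"columns, got {X.shape[1]}"
            )
        return self.model.predict(X)


def retrain_final(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    seed: int,
    endpoint: str = "",
    scale: str = "log10",
    feature_names: list[str] | None = None,
    scaler_state=None,
    train_fingerprints=None,
    estimator: str = "rf",
    cv_result: NestedCVResult | None = None,
) -> ModelBundle:
    """Fit the final model on all annotated compounds with the chosen params."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    est = make_estimator(params, seed, estimator)
    est.fit(X, y)
    return ModelBundle(
        model=est,
        params=dict(params),
        seed=seed,
        endpoint=endpoint,
        scale=scale,
        feature_names=feature_names or [f"f{i}" for i in range(X.shape[1])],
        scaler_state=scaler_state,
        train_fingerprints=train_fingerprints,
        y_train_range=(float(y.min()), float(y.max())),
        cv_result=cv_result,
    )
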