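"""Similarity-based fold-error estimation and applicability-domain alerts.

During nested CV every held-out compound has (a) a natural-scale fold error
and (b) a mean Tanimoto similarity of its 5 nearest neighbours in that fold's
training portion. Binning similarity to 2 decimals and averaging fold errors
per bin yields a similarity → expected-fold-error curve; an RBF kernel ridge
regressor (white-noise magnitude absorbed into the kernel diagonal, which for
kernel ridge is identical to extra ridge regularization) is fit to that curve
with hyperparameters chosen by 10-fold CV maximizing R².

At prediction time a query compound's 5-NN similarity to the final model's
full training set is pushed through the regressor to give an estimated fold
error (clipped below at 1); a similarity below 0.25 raises an
applicability-domain alert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from rdkit.DataStructs import BulkTanimotoSimilarity
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import KFold

from .cv import NestedCVResult, _fold_seed
from .features import morgan_fingerprint

AD_SIMILARITY_THRESHOLD = 0.25


def knn_mean_similarity(query_fp, train_fps, k: int = 5, exclude_self: bool = False) -> float:
    """Mean Tanimoto similarity of the k nearest training neighbours.

    With ``exclude_self`` one maximal (==1.0 identity) hit is removed first,
    for queries that are themselves training members.
    """
    if len(train_fps) == 0:
        raise ValueError("empty training fingerprint set")
    sims = np.array(BulkTanimotoSimilarity(query_fp, list(train_fps)))
    if exclude_self and len(sims) > 1:
        sims = np.delete(sims, int(np.argmax(sims)))
    k = min(k, len(sims))
    top = np.sort(sims)[-k:]
    return float(top.mean())


def collect_similarity_fe_pairs(
    cv_result: NestedCVResult,
    fingerprints: list,
    y: np.ndarray,
    fu_floor: float = 1e-4,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """(similarity, mean fold error) pairs pooled over all CV folds.

    Similarity of each held-out compound is computed against its own fold's
    training portion; fold errors on the natural scale. Compounds are binned
    by similarity rounded to 2 decimals; bins whose similarity lies below
    mean − 1.5·SD of all per-compound similarities are dropped as
    low-similarity outliers.
    """
    y = np.asarray(y, dtype=float)
    sims, fes = [], []
    for fold in cv_result.folds:
        train_fps = [fingerprints[i] for i in fold.train_idx]
        for j, idx in enumerate(fold.test_idx):
            sim = knn_mean_similarity(fingerprints[idx], train_fps, k=k)
            if cv_result.scale == "log10":
                f, obs = 10.0 ** fold.y_pred[j], 10.0 ** y[idx]
            else:
                f = max(fold.y_pred[j], fu_floor)
                obs = max(y[idx], fu_floor)
            fes.append(max(f / obs, obs / f))
            sims.append(sim)
    sims = np.array(sims)
    fes = np.array(fes)
    low_cut = sims.mean() - 1.5 * sims.std(ddof=0)
    bins: dict[float, list[float]] = {}
    for s, fe in zip(np.round(sims, 2), fes):
        bins.setdefault(float(s), []).append(fe)
    xs, ys = [], []
    for s in sorted(bins):
        if s < low_cut:
            continue
        xs.append(s)
        ys.append(float(np.mean(bins[s])))
    return np.array(xs), np.array(ys)


@dataclass
class FoldErrorModel:
    """Fitted similarity → fold-error regressor with AD bookkeeping."""

    regressor: KernelRidge
    train_fingerprints: list
    endpoint: str = ""
    similarity_floor: float = AD_SIMILARITY_THRESHOLD
    best_params: dict = field(default_factory=dict)
    cv_r2: float = float("nan")

    def predict_fold_error(self, similarity: float | np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(similarity, dtype=float)).reshape(-1, 1)
        return np.maximum(self.regressor.predict(x), 1.0)


def _kernel_grid() -> list[dict]:
    length_scales = np.logspace(-2, 1, 4)
    alphas = np.logspace(-3, 1, 5)
    noises = np.logspace(-3, 0, 4)
    return [
        dict(length_scale=l, alpha=a, noise=w)
        for l, a, w in product(length_scales, alphas, noises)
    ]


def fit_fold_error_model(
    similarities: np.ndarray,
    mean_fes: np.ndarray,
    train_fingerprints: list | None = None,
    endpoint: str = "",
    seed: int = 0,
    n_cv_folds: int = 10,
) -> FoldErrorModel:
    """Fit the RBF kernel ridge curve with grid-searched hyperparameters."""
    x = np.asarray(similarities, dtype=float).reshape(-1, 1)
    fe = np.asarray(mean_fes, dtype=float)
    if len(fe) < 20:
        raise ValueError(f"need >= 20 (similarity, fold-error) pairs, got {len(fe)}")
    if np.all(x == x[0]):
        raise ValueError("constant similarity: fold-error curve is degenerate")
    n_cv_folds = min(n_cv_folds, len(fe))
    kf = KFold(n_splits=n_cv_folds, shuffle=True, random_state=seed % (2**31 - 1))
    splits = list(kf.split(x))
    best_score, best_params = -np.inf, None
    for params in _kernel_grid():
        gamma = 1.0 / (2.0 * params["length_scale"] ** 2)
        reg = params["alpha"] + params["noise"]
        scores = []
        for tr, va in splits:
            kr = KernelRidge(kernel="rbf", gamma=gamma, alpha=reg)
            kr.fit(x[tr], fe[tr])
            pred = kr.predict(x[va])
            ss_tot = np.sum((fe[va] - fe[va].mean()) ** 2)
            if ss_tot == 0:
                continue
            scores.append(1.0 - np.sum((fe[va] - pred) ** 2) / ss_tot)
        score = np.mean(scores) if scores else -np.inf
        if score > best_score:
            best_score, best_params = score, params
    gamma = 1.0 / (2.0 * best_params["length_scale"] ** 2)
    final = KernelRidge(kernel="rbf", gamma=gamma, alpha=best_params["alpha"] + best_params["noise"])
    final.fit(x, fe)
    return FoldErrorModel(
        regressor=final,
        train_fingerprints=train_fingerprints or [],
        endpoint=endpoint,
        best_params=dict(best_params),
        cv_r2=float(best_score),
    )


def estimate_fold_error(
    query_smiles: str, fe_model: FoldErrorModel, k: int = 5
) -> tuple[float, float, bool]:
    """(fold error >= 1, 5-NN similarity, AD alert) for one query compound."""
    fp = morgan_fingerprint(query_smiles)
    sim = knn_mean_similarity(fp, fe_model.train_fingerprints, k=k)
    fe = float(fe_model.predict_fold_error(sim)[0])
    alert = sim < fe_model.similarity_floor
    return fe, sim, alert
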