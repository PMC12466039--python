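"""Dataset characterization: similarity profiles, PCA, cross-species
regressions, and clearance stratification.

These analyses describe the chemical and pharmacokinetic space a model was
trained on: how structurally diverse the dataset is (distribution of 5-NN
Tanimoto similarity within the set), how the compounds spread in continuous
descriptor space (PCA), how strongly animal PK translates to human PK on
overlapping compounds (per species × endpoint least-squares R²), and how
prediction quality varies across low/intermediate/high clearance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit.DataStructs import BulkTanimotoSimilarity
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .curation import PKDataset
from .features import FeatureMatrix, morgan_fingerprint
from .metrics import fold_error


@dataclass
class SimilarityProfile:
    mean_5nn: np.ndarray  # per compound
    threshold: float
    fraction_below: float


def similarity_profile(
    std_smiles_list: list[str], threshold: float = 0.30, k: int = 5
) -> SimilarityProfile:
    """Per-compound mean Tanimoto similarity of the 5 nearest in-set neighbours."""
    n = len(std_smiles_list)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} compounds, got {n}")
    fps = [morgan_fingerprint(s) for s in std_smiles_list]
    means = np.empty(n)
    for i in range(n):
        sims = np.array(BulkTanimotoSimilarity(fps[i], fps))
        sims = np.delete(sims, i)  # self excluded
        means[i] = np.sort(sims)[-k:].mean()
    return SimilarityProfile(
        mean_5nn=means,
        threshold=threshold,
        fraction_below=float(np.mean(means < threshold)),
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


def cross_species_regression(
    human: PKDataset, animal: PKDataset, endpoint: str, species: str
) -> RegressionResult:
    """OLS of human endpoint values on one species' values, matched by SMILES.

    Both datasets must already carry their modeling scale (log10 except fu).
    """
    animal_ep = f"{species}_{endpoint}"
    h_vals = {
        s: r.endpoints[endpoint]
        for s, r in zip(human.std_smiles, human.records)
        if endpoint in r.endpoints
    }
    pairs = [
        (r.endpoints[animal_ep], h_vals[s])
        for s, r in zip(animal.std_smiles, animal.records)
        if animal_ep in r.endpoints and s in h_vals
    ]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} overlapping compounds for {animal_ep}")
    x = np.array([p[0] for p in pairs]).reshape(-1, 1)
    y = np.array([p[1] for p in pairs])
    reg = LinearRegression().fit(x, y)
    return RegressionResult(
        slope=float(reg.coef_[0]),
        intercept=float(reg.intercept_),
        r2=float(reg.score(x, y)),
        n=len(pairs),
    )


def continuous_columns(fm: FeatureMatrix) -> np.ndarray:
    """Mask of non-binary columns (a column with <= 2 distinct values is binary)."""
    keep = np.zeros(fm.matrix.shape[1], dtype=bool)
    for j in range(fm.matrix.shape[1]):
        col = fm.matrix[:, j]
        keep[j] = len(np.unique(col[~np.isnan(col)])) > 2
    return keep


def pca_projection(
    fit_block: FeatureMatrix, *project_blocks: FeatureMatrix, n_components: int = 2
) -> tuple[PCA, np.ndarray, list[np.ndarray], np.ndarray]:
    """PCA on the fitting set's continuous descriptors; others projected.

    Returns (fitted PCA, fit scores, projected scores, continuous-column mask).
    Columns are standardized with the fitting set's mean/SD before projection.
    """
    mask = continuous_columns(fit_block)
    X = fit_block.matrix[:, mask]
    mean, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=n_components, random_state=0)
    fit_scores = pca.fit_transform((X - mean) / sd)
    projected = []
    for blk in project_blocks:
        if blk.matrix.shape[1] != fit_block.matrix.shape[1]:
            raise ValueError("projected block must share the fitting block's columns")
        projected.append(pca.transform((blk.matrix[:, mask] - mean) / sd))
    return pca, fit_scores, projected, mask


@dataclass
class ClearanceStrata:
    """Per-stratum counts and 2-fold accuracy for clearance predictions."""

    n_low: int            # CL < 5 mL/min/kg
    pct2_low: float
    n_low_mid: int        # CL < 12 mL/min/kg
    pct2_low_mid: float
    n_high: int           # CL > 20 mL/min/kg
    pct2_high: float
    n_le25: int           # CL <= 25 mL/min/kg
    n_gt25: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def clearance_strata(cl_true: np.ndarray, cl_pred: np.ndarray) -> ClearanceStrata:
    """Stratify 2-fold accuracy by observed clearance (natural mL/min/kg)."""
    cl_true = np.asarray(cl_true, dtype=float)
    cl_pred = np.asarray(cl_pred, dtype=float)
    fe = fold_error(cl_pred, cl_true)

    def stratum(mask: np.ndarray) -> tuple[int, float]:
        n = int(mask.sum())
        pct = float(100.0 * np.mean(fe[mask] <= 2)) if n else float("nan")
        return n, pct

    n_low, p_low = stratum(cl_true < 5)
    n_lm, p_lm = stratum(cl_true < 12)
    n_hi, p_hi = stratum(cl_true > 20)
    return ClearanceStrata(
        n_low=n_low,
        pct2_low=p_low,
        n_low_mid=n_lm,
        pct2_low_mid=p_lm,
        n_high=n_hi,
        pct2_high=p_hi,
        n_le25=int(np.sum(cl_true <= 25)),
        n_gt25=int(np.sum(cl_true > 25)),
    )
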