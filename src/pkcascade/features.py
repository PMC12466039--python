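"""Structural and physicochemical feature blocks with selection and scaling.

Two structure-derived blocks are computed from standardized SMILES:

* ``morgan`` — 2048-bit Morgan fingerprints of radius 2;
* ``physchem`` — the RDKit 2D descriptor set (~210 descriptors computed on
  the pH-7.4 protonated structure).

Selection protocol, fit per species dataset and reused unchanged downstream:
variance filter at 0.05 on the raw values for both blocks, then a greedy
pairwise-correlation filter at 0.95 for the descriptor block only.
Correlation uses signed Pearson r (configurable to |r|), scanning columns in
their canonical order and dropping the later member of each offending pair.
Scaling removes the mean and divides by the SD, fit on the full modeling
dataset before cross-validation splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from .standardize import SmilesParseError

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
)


def _mol(std_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(std_smiles)
    if mol is None:
        raise SmilesParseError(std_smiles)
    return mol


@lru_cache(maxsize=200_000)
def morgan_fingerprint(std_smiles: str) -> ExplicitBitVect:
    """2048-bit Morgan fingerprint (radius 2) as an RDKit bit vector."""
    return _morgan_gen.GetFingerprint(_mol(std_smiles))


@lru_cache(maxsize=200_000)
def _physchem_row(std_smiles: str) -> tuple:
    return tuple(Descriptors.CalcMolDescriptors(_mol(std_smiles)).items())


def morgan_matrix(std_smiles_list: list[str]) -> "FeatureMatrix":
    """Fingerprint block as a compounds × 2048 0/1 matrix."""
    mat = np.zeros((len(std_smiles_list), MORGAN_NBITS), dtype=float)
    for i, smi in enumerate(std_smiles_list):
        fp = morgan_fingerprint(smi)
        mat[i, list(fp.GetOnBits())] = 1.0
    names = [f"morgan_{i}" for i in range(MORGAN_NBITS)]
    return FeatureMatrix("morgan", mat, names)


def physchem_block(std_smiles_list: list[str]) -> "FeatureMatrix":
    """RDKit 2D descriptor block; non-computable values are NaN."""
    rows = [dict(_physchem_row(smi)) for smi in std_smiles_list]
    df = pd.DataFrame(rows)
    mat = df.to_numpy(dtype=float)
    mat[~np.isfinite(mat)] = np.nan
    return FeatureMatrix("physchem", mat, list(df.columns))


@dataclass
class FeatureMatrix:
    """A named feature block with selection and scaling bookkeeping."""

    block_name: str
    matrix: np.ndarray
    feature_names: list[str]
    selection_mask: np.ndarray | None = None  # over the original columns
    scaler_state: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must align with matrix columns")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def subset(self, keep: np.ndarray) -> "FeatureMatrix":
        mask = self.selection_mask
        if mask is None:
            mask = np.ones(self.n_features, dtype=bool)
            new_mask = keep.copy()
        else:
            new_mask = mask.copy()
            new_mask[np.flatnonzero(mask)] = keep
        return FeatureMatrix(
            self.block_name,
            self.matrix[:, keep],
            [n for n, k in zip(self.feature_names, keep) if k],
            selection_mask=new_mask,
        )


def drop_missing_columns(fm: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop columns with any missing value; returns (matrix, dropped names)."""
    keep = ~np.isnan(fm.matrix).any(axis=0)
    dropped = [n for n, k in zip(fm.feature_names, keep) if not k]
    return fm.subset(keep), dropped


def variance_filter(fm: FeatureMatrix, threshold: float = 0.05) -> FeatureMatrix:
    """Retain columns whose population variance is >= threshold."""
    if fm.matrix.size == 0:
        raise ValueError("empty feature matrix")
    variances = np.nanvar(fm.matrix, axis=0, ddof=0)
    return fm.subset(variances >= threshold)


def correlation_filter(
    fm: FeatureMatrix, threshold: float = 0.95, use_abs: bool = False
) -> FeatureMatrix:
    """Greedy left-to-right removal of highly correlated later columns.

    A column is dropped when its Pearson correlation with any already-retained
    earlier column exceeds `threshold` (signed by default).
    """
    X = fm.matrix
    n = X.shape[1]
    if n == 0:
        return fm
    corr = np.corrcoef(X, rowvar=False)
    if use_abs:
        corr = np.abs(corr)
    keep: list[int] = []
    for j in range(n):
        if all(corr[j, i] <= threshold for i in keep):
            keep.append(j)
    mask = np.zeros(n, dtype=bool)
    mask[keep] = True
    return fm.subset(mask)


def fit_scaler(fm: FeatureMatrix) -> FeatureMatrix:
    """Standardize columns to zero mean / unit SD, storing the state."""
    mean = fm.matrix.mean(axis=0)
    sd = fm.matrix.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [n for n, s in zip(fm.feature_names, sd) if s == 0]
        raise ValueError(f"zero-SD columns cannot be scaled: {bad[:5]}")
    out = FeatureMatrix(
        fm.block_name,
        (fm.matrix - mean) / sd,
        list(fm.feature_names),
        selection_mask=fm.selection_mask,
        scaler_state=(mean, sd),
    )
    return out


def apply_scaler(
    fm: FeatureMatrix, scaler_state: tuple[np.ndarray, np.ndarray]
) -> FeatureMatrix:
    mean, sd = scaler_state
    if fm.matrix.shape[1] != mean.shape[0]:
        raise ValueError(
            f"column mismatch: matrix has {fm.matrix.shape[1]}, scaler has {mean.shape[0]}"
        )
    return FeatureMatrix(
        fm.block_name,
        (fm.matrix - mean) / sd,
        list(fm.feature_names),
        selection_mask=fm.selection_mask,
        scaler_state=(mean, sd),
    )


@dataclass
class FeatureRecipe:
    """Frozen per-dataset featurization: selected columns + imputation means.

    Fit once on a species' modeling dataset; applied unchanged to any query
    compounds (external test set, human compounds fed to animal models).
    Missing descriptor values at prediction time are imputed with the
    training-set column mean.
    """

    morgan_names: list[str] = field(default_factory=list)
    physchem_names: list[str] = field(default_factory=list)
    physchem_impute: np.ndarray | None = None
    variance_threshold: float = 0.05
    correlation_threshold: float = 0.95

    def fit(self, std_smiles_list: list[str]) -> "FeatureRecipe":
        morgan = variance_filter(
            morgan_matrix(std_smiles_list), self.variance_threshold
        )
        physchem, _dropped = drop_missing_columns(physchem_block(std_smiles_list))
        physchem = variance_filter(physchem, self.variance_threshold)
        physchem = correlation_filter(physchem, self.correlation_threshold)
        self.morgan_names = list(morgan.feature_names)
        self.physchem_names = list(physchem.feature_names)
        self.physchem_impute = np.nanmean(physchem.matrix, axis=0)
        return self

    def transform_blocks(
        self, std_smiles_list: list[str]
    ) -> tuple[FeatureMatrix, FeatureMatrix]:
        """(morgan, physchem) blocks under the fitted selection, imputed."""
        morgan_all = morgan_matrix(std_smiles_list)
        m_idx = [morgan_all.feature_names.index(n) for n in self.morgan_names]
        morgan = FeatureMatrix(
            "morgan", morgan_all.matrix[:, m_idx], list(self.morgan_names)
        )

        phys_all = physchem_block(std_smiles_list)
        p_idx = [phys_all.feature_names.index(n) for n in self.physchem_names]
        phys = phys_all.matrix[:, p_idx]
        nan_mask = np.isnan(phys)
        if nan_mask.any():
            phys[nan_mask] = np.broadcast_to(self.physchem_impute, phys.shape)[nan_mask]
        physchem = FeatureMatrix("physchem", phys, list(self.physchem_names))
        return morgan, physchem

    def transform(self, std_smiles_list: list[str]) -> FeatureMatrix:
        """Concatenated (morgan | physchem) block under the fitted selection."""
        morgan, physchem = self.transform_blocks(std_smiles_list)
        return FeatureMatrix(
            "morgan+physchem",
            np.hstack([morgan.matrix, physchem.matrix]),
            self.morgan_names + self.physchem_names,
        )
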