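"""Curation of raw compound/PK tables into modeling-ready datasets.

The curation protocol, applied per species table:

1. standardize every SMILES (sanitize, normalize, largest fragment,
   canonical tautomer, pH-7.4 protonation); unparsable records are dropped
   with a logged warning and counted in the curation report;
2. merge duplicate standardized SMILES, taking the per-endpoint median of
   the available values;
3. drop compounds whose exact molecular weight exceeds mean + 1.5 SD of the
   merged dataset (upper bound only — the filter exists to remove large
   outliers, small molecules are the point);
4. decadic-log transform every endpoint except fu (fraction unbound is a
   bounded fraction and is modeled raw).

fu values of exactly 0 are treated as missing: a zero fraction unbound
cannot enter any fold-error computation and is physically a censored value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .standardize import SmilesParseError, exact_mol_weight, standardize_smiles

logger = logging.getLogger(__name__)

HUMAN_ENDPOINTS = ("VDss", "CL", "t_half", "fu", "MRT")
ANIMAL_SPECIES = ("rat", "dog", "monkey")
ANIMAL_PK = ("VDss", "CL", "fu")
ANIMAL_ENDPOINTS = tuple(f"{sp}_{ep}" for sp in ANIMAL_SPECIES for ep in ANIMAL_PK)

#: endpoints never log-transformed (bounded fractions)
RAW_SCALE_ENDPOINTS = frozenset(
    {"fu"} | {f"{sp}_fu" for sp in ANIMAL_SPECIES}
)

UNITS = {
    "VDss": "L/kg",
    "CL": "mL/min/kg",
    "t_half": "h",
    "fu": "",
    "MRT": "h",
}


def endpoint_scale(endpoint: str) -> str:
    """Model scale for an endpoint: 'raw' for fraction unbound, else 'log10'."""
    return "raw" if endpoint in RAW_SCALE_ENDPOINTS else "log10"


@dataclass
class CompoundRecord:
    raw_smiles: str
    std_smiles: str
    mol_weight: float
    endpoints: dict[str, float] = field(default_factory=dict)


@dataclass
class PKDataset:
    """A curated per-species table of compounds × endpoints.

    ``records`` is keyed implicitly by ``std_smiles`` (unique after merging);
    ``log_transformed`` tracks which endpoint columns hold log10 values.
    """

    species: str
    records: list[CompoundRecord]
    endpoint_names: tuple[str, ...]
    log_transformed: set[str] = field(default_factory=set)

    def __post_init__(self):
        smiles = [r.std_smiles for r in self.records]
        if len(smiles) != len(set(smiles)):
            raise ValueError("std_smiles must be unique within a dataset")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def std_smiles(self) -> list[str]:
        return [r.std_smiles for r in self.records]

    def endpoint_values(self, endpoint: str) -> np.ndarray:
        """Values of one endpoint aligned to record order; NaN where missing."""
        return np.array(
            [r.endpoints.get(endpoint, np.nan) for r in self.records], dtype=float
        )

    def annotated_mask(self, endpoint: str) -> np.ndarray:
        return ~np.isnan(self.endpoint_values(endpoint))

    def sparsity(self) -> float:
        """Fraction of missing compound × endpoint cells."""
        total = len(self.records) * len(self.endpoint_names)
        if total == 0:
            return 0.0
        annotated = sum(
            int(self.annotated_mask(ep).sum()) for ep in self.endpoint_names
        )
        return 1.0 - annotated / total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"std_smiles": r.std_smiles, "mol_weight": r.mol_weight}
            for ep in self.endpoint_names:
                row[ep] = r.endpoints.get(ep, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CurationReport:
    species: str
    n_input: int
    n_parse_failures: int
    n_after_merge: int
    n_mw_removed: int
    mw_threshold: float
    n_final: int
    sparsity: float
    n_annotated: dict[str, int]

    def as_dict(self) -> dict:
        return self.__dict__.copy()


class InsufficientDataError(ValueError):
    pass


def standardize_table(
    df: pd.DataFrame,
    endpoint_names: tuple[str, ...],
    smiles_col: str = "smiles",
) -> tuple[list[CompoundRecord], int]:
    """Standardize every row; returns (records, parse-failure count)."""
    records: list[CompoundRecord] = []
    failures = 0
    for _, row in df.iterrows():
        raw = str(row[smiles_col])
        try:
            std = standardize_smiles(raw)
        except SmilesParseError as exc:
            failures += 1
            logger.warning("dropping unstandardizable SMILES: %s", exc)
            continue
        endpoints = {}
        for ep in endpoint_names:
            if ep not in row or pd.isna(row[ep]):
                continue
            val = float(row[ep])
            if ep in RAW_SCALE_ENDPOINTS and val == 0.0:
                logger.warning("treating fu == 0 as missing for %s", std)
                continue
            endpoints[ep] = val
        records.append(
            CompoundRecord(
                raw_smiles=raw,
                std_smiles=std,
                mol_weight=exact_mol_weight(std),
                endpoints=endpoints,
            )
        )
    return records, failures


def merge_duplicates(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """One record per unique std_smiles; per-endpoint median of available values."""
    by_smiles: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        by_smiles.setdefault(rec.std_smiles, []).append(rec)
    merged = []
    for std, group in by_smiles.items():
        endpoints: dict[str, float] = {}
        keys = {k for rec in group for k in rec.endpoints}
        for key in keys:
            vals = [rec.endpoints[key] for rec in group if key in rec.endpoints]
            endpoints[key] = float(np.median(vals))
        merged.append(
            CompoundRecord(
                raw_smiles=group[0].raw_smiles,
                std_smiles=std,
                mol_weight=group[0].mol_weight,
                endpoints=endpoints,
            )
        )
    return merged


def mw_filter(dataset: PKDataset, k: float = 1.5) -> tuple[PKDataset, float]:
    """Drop records with mol_weight > mean + k·SD; returns (dataset, threshold)."""
    if len(dataset) < 2:
        raise InsufficientDataError("molecular-weight filter needs >= 2 records")
    weights = np.array([r.mol_weight for r in dataset.records])
    threshold = float(weights.mean() + k * weights.std(ddof=0))
    kept = [r for r in dataset.records if r.mol_weight <= threshold]
    out = PKDataset(
        species=dataset.species,
        records=kept,
        endpoint_names=dataset.endpoint_names,
        log_transformed=set(dataset.log_transformed),
    )
    return out, threshold


def log_transform(dataset: PKDataset) -> PKDataset:
    """Replace every endpoint except fu with its decadic logarithm."""
    transformable = [
        ep for ep in dataset.endpoint_names if ep not in RAW_SCALE_ENDPOINTS
    ]
    new_records = []
    for rec in dataset.records:
        endpoints = {}
        for ep, val in rec.endpoints.items():
            if ep in transformable:
                if val <= 0:
                    raise ValueError(
                        f"non-positive value {val} for endpoint {ep} of {rec.std_smiles}"
                    )
                endpoints[ep] = math.log10(val)
            else:
                endpoints[ep] = val
        new_records.append(
            CompoundRecord(rec.raw_smiles, rec.std_smiles, rec.mol_weight, endpoints)
        )
    return PKDataset(
        species=dataset.species,
        records=new_records,
        endpoint_names=dataset.endpoint_names,
        log_transformed=set(dataset.log_transformed) | set(transformable),
    )


def inverse_log_transform(dataset: PKDataset) -> PKDataset:
    new_records = []
    for rec in dataset.records:
        endpoints = {
            ep: (10.0 ** v if ep in dataset.log_transformed else v)
            for ep, v in rec.endpoints.items()
        }
        new_records.append(
            CompoundRecord(rec.raw_smiles, rec.std_smiles, rec.mol_weight, endpoints)
        )
    return PKDataset(
        species=dataset.species,
        records=new_records,
        endpoint_names=dataset.endpoint_names,
        log_transformed=set(),
    )


def remove_overlap(test: PKDataset, train: PKDataset) -> PKDataset:
    """Keep only test records whose std_smiles is absent from train."""
    train_smiles = set(train.std_smiles)
    kept = [r for r in test.records if r.std_smiles not in train_smiles]
    return PKDataset(
        species=test.species,
        records=kept,
        endpoint_names=test.endpoint_names,
        log_transformed=set(test.log_transformed),
    )


def curate_dataset(
    df: pd.DataFrame,
    species: str,
    endpoint_names: tuple[str, ...],
    smiles_col: str = "smiles",
    mw_k: float = 1.5,
    apply_log: bool = True,
) -> tuple[PKDataset, CurationReport]:
    """Full curation pipeline: standardize → merge → MW filter → log transform."""
    records, failures = standardize_table(df, endpoint_names, smiles_col)
    merged = merge_duplicates(records)
    dataset = PKDataset(species=species, records=merged, endpoint_names=endpoint_names)
    if len(dataset) >= 2:
        dataset, threshold = mw_filter(dataset, k=mw_k)
    else:  # SD undefined: nothing to filter against
        threshold = float("inf")
    n_mw_removed = len(merged) - len(dataset)
    if apply_log:
        dataset = log_transform(dataset)
    report = CurationReport(
        species=species,
        n_input=len(df),
        n_parse_failures=failures,
        n_after_merge=len(merged),
        n_mw_removed=n_mw_removed,
        mw_threshold=threshold,
        n_final=len(dataset),
        sparsity=dataset.sparsity(),
        n_annotated={
            ep: int(dataset.annotated_mask(ep).sum()) for ep in endpoint_names
        },
    )
    return dataset, report
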