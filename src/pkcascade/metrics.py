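"""Evaluation metrics for pharmacokinetic regression models.

Fold-error statistics (FE, 2/3/5-fold %, MFE, GMFE, ALB, bias) operate on
natural-scale values: log-scale predictions must be antilogged (10**x) before
they are passed in. RMSE and R² operate on whatever scale the model was fit
on (log10 for VDss/CL/t½/MRT, raw for fu).

GMFE is computed from absolute log10 fold errors, the standard PK convention,
so GMFE >= 1 always; the signed average logarithmic bias is exposed separately
as ``alb_signed`` (GMFE == 10**mean(|log10 FE|), not 10**alb_signed unless all
errors share a sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats


def _as_positive(f, y) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    if f.shape != y.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {y.shape}")
    if f.size == 0:
        raise ValueError("empty prediction set")
    if np.any(f <= 0) or np.any(y <= 0):
        raise ValueError("fold-error metrics require strictly positive natural-scale values")
    return f, y


def fold_error(f, y) -> np.ndarray | float:
    """Symmetric fold error max(f/y, y/f); 1 means a perfect prediction."""
    scalar = np.isscalar(f) and np.isscalar(y)
    f, y = _as_positive(np.atleast_1d(f), np.atleast_1d(y))
    fe = np.maximum(f / y, y / f)
    return float(fe[0]) if scalar else fe


def gmfe(f, y) -> float:
    """Geometric mean fold error: 10 ** mean(|log10(f/y)|)."""
    f, y = _as_positive(f, y)
    return float(10.0 ** np.mean(np.abs(np.log10(f / y))))


def alb_signed(f, y) -> float:
    """Signed average logarithmic bias: mean(log10(f/y))."""
    f, y = _as_positive(f, y)
    return float(np.mean(np.log10(f / y)))


def mfe(f, y) -> float:
    """Median fold error."""
    return float(np.median(fold_error(np.atleast_1d(f), np.atleast_1d(y))))


def pct_within_fold(f, y, k: float) -> float:
    """Percentage of predictions with fold error <= k (boundary inclusive)."""
    fe = fold_error(np.atleast_1d(f), np.atleast_1d(y))
    return float(100.0 * np.mean(fe <= k))


def bias(f, y) -> float:
    """Median signed error median(f_i - y_i), on the scale the values are given."""
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(f - y))


def rmse(f, y) -> float:
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((y - f) ** 2)))


def r2(f, y) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; NaN when y is constant."""
    f = np.asarray(f, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - np.sum((y - f) ** 2) / ss_tot)


@dataclass
class MetricsReport:
    """All evaluation metrics for one prediction set.

    ``pct_within_*``, ``mfe``, ``gmfe``, ``alb``, ``bias_natural`` are computed
    on the natural scale; ``rmse``, ``r2``, ``bias`` on the model scale.
    """

    n: int
    pct_within_2fold: float
    pct_within_3fold: float
    pct_within_5fold: float
    mfe: float
    gmfe: float
    alb: float
    bias: float
    rmse: float
    r2: float
    endpoint: str = ""
    r2_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(
    y_true,
    y_pred,
    scale: str = "log10",
    endpoint: str = "",
    fu_floor: float = 1e-4,
) -> MetricsReport:
    """Compute the full metrics report for one fold / test set.

    Parameters
    ----------
    y_true, y_pred : array-like
        Observations and predictions on the model scale (`scale`).
    scale : {"log10", "raw"}
        "log10": RMSE/R²/bias on the given values, fold metrics after 10**x.
        "raw": all metrics on the given values (fu); values floored at
        `fu_floor` before fold-error computation.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if scale == "log10":
        nat_true, nat_pred = 10.0 ** y_true, 10.0 ** y_pred
    elif scale == "raw":
        nat_true = np.maximum(y_true, fu_floor)
        nat_pred = np.maximum(y_pred, fu_floor)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    r2_val = r2(y_pred, y_true)
    return MetricsReport(
        n=int(y_true.size),
        pct_within_2fold=pct_within_fold(nat_pred, nat_true, 2),
        pct_within_3fold=pct_within_fold(nat_pred, nat_true, 3),
        pct_within_5fold=pct_within_fold(nat_pred, nat_true, 5),
        mfe=mfe(nat_pred, nat_true),
        gmfe=gmfe(nat_pred, nat_true),
        alb=alb_signed(nat_pred, nat_true),
        bias=bias(y_pred, y_true),
        rmse=rmse(y_pred, y_true),
        r2=0.0 if np.isnan(r2_val) else r2_val,
        endpoint=endpoint,
        r2_defined=not np.isnan(r2_val),
    )


def paired_gmfe_ttest(gmfe_a: Sequence[float], gmfe_b: Sequence[float]) -> tuple[float, float]:
    """Paired t-test over per-fold GMFEs of two models evaluated on the same folds.

    Returns (t statistic, two-sided p value). Negative t means model A has the
    lower (better) GMFE.
    """
    a = np.asarray(gmfe_a, dtype=float)
    b = np.asarray(gmfe_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold GMFE vectors must align")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
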