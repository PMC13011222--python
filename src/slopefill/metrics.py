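"""Imputation scoring (R², MAE, RMSE) and the CV volatility diagnostic.

Scores are computed over the masked positions only: the quantities of
interest are the errors at the points the method actually had to
reconstruct, and observed values are preserved exactly by every method
here, so whole-series scoring would merely dilute the errors with
zeros.  Whole-series scoring remains available via ``scope="all"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import ImputationResult, TimeSeries
from .simulate import MissingMask

__all__ = [
    "MetricsReport",
    "CVResult",
    "score",
    "score_imputation",
    "coefficient_of_variation",
    "error_table",
]


@dataclass(frozen=True)
class MetricsReport:
    """R² (dimensionless), MAE and RMSE (µg/m³) over scored positions.

    RMSE ≥ MAE always (power-mean inequality); R² can be negative when
    the reconstruction is worse than predicting the mean, and is NaN
    when the truth is constant.
    """

    r2: float
    mae: float
    rmse: float
    n_scored: int


def score(truth, imputed) -> MetricsReport:
    """Score imputed values against ground truth at the same positions.

    R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)² with ȳ the mean of the truth over the
    scored positions; MAE and RMSE are the usual L1/L2 means.
    """
    y = np.asarray(truth, dtype=float)
    yhat = np.asarray(imputed, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: truth {y.size}, imputed {yhat.size}")
    if y.size == 0:
        raise ValueError("cannot score zero positions")
    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn(
            "truth is constant over the scored positions; R² is undefined",
            UserWarning,
            stacklevel=2,
        )
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return MetricsReport(r2=r2, mae=mae, rmse=rmse, n_scored=int(y.size))


def score_imputation(
    truth: TimeSeries,
    result: ImputationResult,
    mask: MissingMask,
    scope: str = "masked",
) -> MetricsReport:
    """Score a reconstruction against the original complete series.

    ``scope="masked"`` (default) evaluates only the masked positions;
    ``scope="all"`` evaluates every position.  An empty mask means
    there was nothing to reconstruct, which counts as a perfect score.
    """
    if scope == "masked":
        idx = np.asarray(mask.indices, dtype=int)
        if idx.size == 0:
            return MetricsReport(r2=1.0, mae=0.0, rmse=0.0, n_scored=0)
        return score(truth.values[idx], result.series.values[idx])
    if scope == "all":
        return score(truth.values, result.series.values)
    raise ValueError(f"unknown scope: {scope!r}")


class CVResult(NamedTuple):
    cv: float
    category: str


def coefficient_of_variation(series) -> CVResult:
    """Sample coefficient of variation of the observed values.

    CV = s/x̄ with s the sample standard deviation (denominator N−1).
    The volatility category follows the conventional three-level rule:
    low (CV < 0.2), moderate (0.2 ≤ CV ≤ 0.5), high (CV > 0.5).
    """
    if isinstance(series, TimeSeries):
        values = series.observed_values
    else:
        values = np.asarray(series, dtype=float)
        values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("CV needs at least two observed values")
    mean = float(values.mean())
    if mean == 0.0:
        raise ValueError("CV undefined: mean of observed values is zero")
    cv = float(values.std(ddof=1)) / mean
    if cv < 0.2:
        category = "low"
    elif cv <= 0.5:
        category = "moderate"
    else:
        category = "high"
    return CVResult(cv=cv, category=category)


def error_table(
    truth: TimeSeries,
    result: ImputationResult,
    mask: MissingMask,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-record error table at the masked positions.

    Columns: date, original, imputed, error (imputed − original) and
    percent_error (100·error/original), both rounded half-even to
    ``decimals`` places to match conventional table formatting.  Rows
    whose original value is zero get NaN percent error and a warning.
    """
    idx = np.asarray(mask.indices, dtype=int)
    original = truth.values[idx]
    imputed = result.series.values[idx]
    error = imputed - original
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(original != 0, 100.0 * error / original, np.nan)
    if idx.size and (original == 0).any():
        warnings.warn(
            "percent error undefined where the original value is zero",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "date": truth.times[idx],
            "original": original,
            "imputed": imputed,
            "error": np.round(error, decimals),
            "percent_error": np.round(pct, decimals),
        }
    )
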