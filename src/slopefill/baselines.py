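"""Comparator imputation methods: interpolating splines and value clipping.

The spline baselines (degree 1, 2, 3) fit one interpolating spline
through *all* observed points and evaluate it at the missing times —
the configuration whose overshoot near sharp peaks motivates the
slope-constrained method.  The ``clipped_extreme`` ablation isolates
what a slope constraint adds over naive range control: it linearly
interpolates, then clamps each imputed *value* into a global percentile
band of the observed values, with no slope logic at all.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import make_interp_spline

from .core import (
    ClipRecord,
    ImputationResult,
    InsufficientDataError,
    TimeSeries,
    UnboundedGapError,
    find_gaps,
    linear_fill,
    unbounded_runs,
)

__all__ = ["BASELINE_NAMES", "spline_impute", "clipped_extreme_impute"]

BASELINE_NAMES = ("linear", "quadratic", "cubic", "clipped_extreme")

_DEGREE_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}


def _boundary_fill(series: TimeSeries, out: np.ndarray, boundary: str) -> list[ClipRecord]:
    """Shared leading/trailing-run policy: error, or nearest-value fill."""
    leading, trailing = unbounded_runs(series)
    log: list[ClipRecord] = []
    if not (leading.size or trailing.size):
        return log
    if boundary == "error":
        raise UnboundedGapError(
            "missing run at the series boundary has no observed anchor; "
            "pass boundary='nearest' to fill with the nearest observed value"
        )
    if boundary != "nearest":
        raise ValueError(f"unknown boundary policy: {boundary!r}")
    obs_idx = np.flatnonzero(~np.isnan(series.values))
    for run, anchor in ((leading, obs_idx[0]), (trailing, obs_idx[-1])):
        fill = float(series.values[anchor])
        for idx in run:
            out[idx] = fill
            log.append(
                ClipRecord(
                    index=int(idx),
                    time=series.times[idx],
                    linear_value=fill,
                    final_value=fill,
                    clipped=False,
                    applied_slope=0.0,
                    boundary=True,
                )
            )
    return log


def spline_impute(
    series: TimeSeries, degree: int, *, boundary: str = "error"
) -> ImputationResult:
    """Impute by an interpolating spline of the given degree (1, 2 or 3).

    The spline passes through every observed point exactly (it
    interpolates, it does not smooth), so observed values are preserved;
    missing interior points take the spline's value there.
    """
    if degree not in _DEGREE_NAMES:
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    v = series.values
    obs_idx = np.flatnonzero(~np.isnan(v))
    if obs_idx.size < degree + 1:
        raise InsufficientDataError(
            f"{_DEGREE_NAMES[degree]} spline needs at least {degree + 1} "
            f"observed points, got {obs_idx.size}"
        )
    out = v.copy()
    log = _boundary_fill(series, out, boundary)

    gaps = find_gaps(series)
    missing = np.concatenate([g.missing_indices for g in gaps]) if gaps else np.array([], dtype=int)
    if missing.size:
        spline = make_interp_spline(obs_idx, v[obs_idx], k=degree)
        filled = spline(missing)
        out[missing] = filled
        for idx, val in zip(missing, filled):
            log.append(
                ClipRecord(
                    index=int(idx),
                    time=series.times[idx],
                    linear_value=float(val),
                    final_value=float(val),
                    clipped=False,
                    applied_slope=float("nan"),
                )
            )
    log.sort(key=lambda r: r.index)
    return ImputationResult(
        series=TimeSeries(series.times, out),
        clip_log=log,
        threshold=None,
        gap_diagnostics=[],
        n_operations=len(log),
    )


def clipped_extreme_impute(
    series: TimeSeries,
    p: float = 95.0,
    *,
    two_sided: bool = True,
    boundary: str = "error",
) -> ImputationResult:
    """Linear interpolation followed by a global value clamp.

    Each imputed value is clamped into the band
    [Percentile₁₀₀₋ₚ(observed), Percentileₚ(observed)] (lower bound
    dropped when ``two_sided`` is False).  The band is computed once
    from the observed values of the input.  Unlike the slope-constrained
    method this governs only the range of imputed values, not the
    dynamics between consecutive points.
    """
    if not 0 < p <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {p}")
    v = series.values
    obs = v[~np.isnan(v)]
    if obs.size < 2:
        raise InsufficientDataError("need at least two observed values")
    hi = float(np.percentile(obs, p))
    lo = float(np.percentile(obs, 100.0 - p)) if two_sided else -np.inf

    out = v.copy()
    log = _boundary_fill(series, out, boundary)
    for gap in find_gaps(series):
        lin = linear_fill(gap)
        final = np.clip(lin, lo, hi)
        out[gap.missing_indices] = final
        for idx, lv, fv in zip(gap.missing_indices, lin, final):
            log.append(
                ClipRecord(
                    index=int(idx),
                    time=series.times[idx],
                    linear_value=float(lv),
                    final_value=float(fv),
                    clipped=bool(fv != lv),
                    applied_slope=float("nan"),
                )
            )
    log.sort(key=lambda r: r.index)
    return ImputationResult(
        series=TimeSeries(series.times, out),
        clip_log=log,
        threshold=None,
        gap_diagnostics=[],
        n_operations=len(log),
    )
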