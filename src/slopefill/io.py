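"""Reading and writing the two-column delimited series format.

The on-disk format is a header line ``date,value`` followed by one row
per day: an ISO-8601 date (or a plain integer index) and a numeric
concentration, with an empty field, ``NA`` or ``NaN`` marking a missing
value.  Floats are written at full repr precision so a read→write→read
round trip is lossless.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bench import EvaluationReport
from .core import ImputationResult, TimeSeries

__all__ = [
    "MISSING_TOKENS",
    "read_series",
    "write_series",
    "write_audit",
    "write_report",
]

MISSING_TOKENS = ("", "NA", "NaN")


def read_series(path, delimiter: str = ",") -> TimeSeries:
    """Read a two-column delimited file into a :class:`TimeSeries`.

    The first column holds ISO-8601 dates (or integer indices), the
    second the values; missing tokens ({"", "NA", "NaN"}) become NaN.
    Uniform daily (unit) spacing is validated; a non-numeric value is
    reported with its line number.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, found {df.shape[1]}")
    raw_times = df.iloc[:, 0].str.strip()
    raw_values = df.iloc[:, 1].str.strip()

    values = np.empty(len(df), dtype=float)
    for i, token in enumerate(raw_values):
        if token in MISSING_TOKENS:
            values[i] = math.nan
            continue
        try:
            values[i] = float(token)
        except ValueError as exc:
            # +2: one for the header, one for 1-based numbering
            raise ValueError(
                f"{path}, line {i + 2}: unparseable value {token!r}"
            ) from exc

    try:
        times = raw_times.astype("int64").to_numpy()
    except ValueError:
        try:
            times = pd.to_datetime(raw_times, format="ISO8601").to_numpy().astype(
                "datetime64[D]"
            )
        except ValueError as exc:
            raise ValueError(f"{path}: first column is neither integer nor ISO-8601 dates") from exc
    return TimeSeries(times, values)


def _series_frame(series: TimeSeries) -> pd.DataFrame:
    return pd.DataFrame({"date": series.times, "value": series.values})


def write_series(obj, path, delimiter: str = ",", audit_path=None) -> None:
    """Write a series, imputation result or evaluation report.

    Dispatches on type.  For an :class:`ImputationResult`, the
    reconstructed series goes to ``path``; if ``audit_path`` is given
    and the clip log is non-empty, the per-point audit is written there
    as a sidecar (an empty log emits no sidecar).
    """
    if isinstance(obj, TimeSeries):
        _series_frame(obj).to_csv(path, sep=delimiter, index=False, na_rep="")
    elif isinstance(obj, ImputationResult):
        _series_frame(obj.series).to_csv(path, sep=delimiter, index=False, na_rep="")
        if audit_path is not None and obj.clip_log:
            write_audit(obj.clip_log, audit_path, delimiter=delimiter)
    elif isinstance(obj, EvaluationReport):
        write_report(obj, path, delimiter=delimiter)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def write_audit(clip_log, path, delimiter: str = ",") -> None:
    """Write the per-imputed-point audit log as delimited text."""
    frame = pd.DataFrame([asdict(r) for r in clip_log])
    frame = frame.rename(columns={"linear_value": "linear", "final_value": "final"})
    cols = ["index", "time", "linear", "final", "clipped", "applied_slope", "boundary"]
    frame[cols].to_csv(path, sep=delimiter, index=False)


def write_report(report: EvaluationReport, path, delimiter: str = ",") -> None:
    """Write per-run rows; the summary goes to a ``.summary`` sidecar."""
    path = Path(path)
    report.rows.to_csv(path, sep=delimiter, index=False)
    summary_path = path.with_suffix(path.suffix + ".summary")
    report.summary.to_csv(summary_path, sep=delimiter, index=False)
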