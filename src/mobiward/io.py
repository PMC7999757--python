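"""Readers and writers for sensor streams, label intervals and result tables.

All interchange is plain CSV:

* sensor stream: ``timestamp,ax_g,ay_g,az_g`` (ISO-8601 timestamps)
* label intervals: ``start,end,label_code``
* daily summaries: one row per patient-day with minutes and percentage
  columns per activity.
"""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np
import pandas as pd

from .types import (
    ACTIVITY_NAMES,
    ActivityLabel,
    LabelInterval,
    SensorTrace,
    ValidationError,
)
from .ward import DailySummary

log = logging.getLogger(__name__)

SENSOR_COLUMNS = ["timestamp", "ax_g", "ay_g", "az_g"]
LABEL_COLUMNS = ["start", "end", "label_code"]

#: standard gravity, used when converting m/s^2 inputs to g
G_PER_MS2 = 1.0 / 9.81


def read_sensor_csv(path, site: str, units: str = "g") -> SensorTrace:
    """Read a tri-axial acceleration stream.

    The sample rate is inferred from the median inter-sample interval;
    sampling gaps longer than twice the nominal period are counted and
    logged, not repaired (resample to obtain a strictly uniform grid).

    Parameters
    ----------
    path
        CSV file with header ``timestamp,ax_g,ay_g,az_g``.
    site
        ``"arm"`` or ``"leg"``.
    units
        ``"g"`` (default) or ``"m/s2"``; the latter is divided by 9.81.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty sensor file") from None
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")

    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamp ({exc})") from None
    axes = np.empty((len(df), 3), dtype=float)
    for j, col in enumerate(SENSOR_COLUMNS[1:]):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            # +2: header line plus 1-based indexing
            raise ValidationError(f"{path}: malformed value in column {col}, line {bad[0] + 2}")
        axes[:, j] = vals
    if units == "m/s2":
        axes = axes * G_PER_MS2
    elif units != "g":
        raise ValidationError(f"unknown units {units!r}; use 'g' or 'm/s2'")

    dt = np.diff(ts.to_numpy().astype("datetime64[ns]").astype(np.int64)) / 1e9
    if len(dt) == 0:
        raise ValidationError(f"{path}: at least two samples required to infer the rate")
    if np.any(dt <= 0):
        i = int(np.flatnonzero(dt <= 0)[0])
        raise ValidationError(f"{path}: non-monotone timestamps at line {i + 3}")
    period = float(np.median(dt))
    rate = 1.0 / period
    n_gaps = int(np.sum(dt > 2.0 * period))
    if n_gaps:
        log.warning("%s: %d sampling gap(s) longer than twice the nominal period", path, n_gaps)
    trace = SensorTrace(site=site, sample_rate_hz=rate, start_time=ts.iloc[0], samples=axes)
    trace.n_gaps = n_gaps  # annotation for callers that want the gap count
    return trace


def write_sensor_csv(trace: SensorTrace, path) -> None:
    """Write a trace in the sensor CSV interchange format."""
    df = pd.DataFrame(trace.samples, columns=SENSOR_COLUMNS[1:])
    df.insert(0, "timestamp", trace.times().strftime("%Y-%m-%dT%H:%M:%S.%f"))
    df.to_csv(path, index=False, float_format="%.6f")


def read_labels(path) -> List[LabelInterval]:
    """Read and validate activity label intervals, returned time-sorted."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty label file") from None
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    intervals = []
    for _, row in df.iterrows():
        code = int(row["label_code"])
        if code not in ACTIVITY_NAMES:
            raise ValidationError(f"{path}: unknown activity code {code}")
        intervals.append(
            LabelInterval(
                start_time=pd.Timestamp(row["start"]),
                end_time=pd.Timestamp(row["end"]),
                label=ActivityLabel(code),
            )
        )
    intervals.sort(key=lambda iv: iv.start_time)
    for a, b in zip(intervals, intervals[1:]):
        if b.start_time < a.end_time:
            raise ValidationError(
                f"{path}: overlapping intervals at {b.start_time} (previous ends {a.end_time})"
            )
    return intervals


def write_labels(intervals: Sequence[LabelInterval], path) -> None:
    df = pd.DataFrame(
        {
            "start": [iv.start_time.isoformat() for iv in intervals],
            "end": [iv.end_time.isoformat() for iv in intervals],
            "label_code": [iv.label.code for iv in intervals],
        }
    )
    df.to_csv(path, index=False)


def _summary_columns() -> List[str]:
    names = [ACTIVITY_NAMES[c] for c in sorted(ACTIVITY_NAMES)]
    return (
        ["patient_id", "sex", "day_index"]
        + [f"min_{n}" for n in names]
        + [f"pct_{n}" for n in names]
        + ["observed_minutes"]
    )


def write_daily_summaries(summaries: Sequence[DailySummary], path) -> None:
    """Write one CSV row per patient-day (minutes and percentage per activity)."""
    rows = []
    for s in summaries:
        row = {"patient_id": s.patient_id, "sex": s.sex, "day_index": s.day_index}
        for c in sorted(ACTIVITY_NAMES):
            name = ACTIVITY_NAMES[c]
            row[f"min_{name}"] = s.minutes[c]
            row[f"pct_{name}"] = s.percentages[c] if s.percentages is not None else np.nan
        row["observed_minutes"] = s.observed_minutes
        rows.append(row)
    pd.DataFrame(rows, columns=_summary_columns()).to_csv(path, index=False, float_format="%.6f")


def read_daily_summaries(path) -> List[DailySummary]:
    df = pd.read_csv(path)
    missing = [c for c in _summary_columns() if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        minutes = {c: float(row[f"min_{ACTIVITY_NAMES[c]}"]) for c in sorted(ACTIVITY_NAMES)}
        pct_vals = {c: float(row[f"pct_{ACTIVITY_NAMES[c]}"]) for c in sorted(ACTIVITY_NAMES)}
        observed = float(row["observed_minutes"])
        out.append(
            DailySummary(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                day_index=int(row["day_index"]),
                minutes=minutes,
                percentages=None if observed == 0 else pct_vals,
                observed_minutes=observed,
            )
        )
    return out


def write_feature_matrix(features: np.ndarray, names: Sequence[str], path) -> None:
    pd.DataFrame(features, columns=list(names)).to_csv(path, index=False, float_format="%.8g")


def read_feature_matrix(path):
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)
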