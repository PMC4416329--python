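"""Reading CGM exports and writing reports.

Two input dialects are supported:

* a *generic* delimited table with named timestamp and glucose columns
  (:func:`read_generic_csv`) — the lowest common denominator any CGM export
  can be reduced to;
* a *CareLink-style* export (:func:`read_carelink_export`): a delimited
  re-export of the vendor's table, with a preamble, many columns, and sensor
  glucose in a recognisable column among calibration/alarm rows.  Native
  binary ``.xls`` is out of scope — re-export the same columns as CSV.

All parsing funnels into a sorted, deduplicated
:class:`~glyvar.series.GlucoseSeries`; rows with an empty glucose cell are
dropped here and resurface as grid gaps downstream.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputFormatError
from .report import VariabilityReport
from .series import GlucoseSeries, Unit

#: Column names recognised as sensor glucose in CareLink-style exports,
#: tried in order.  The unit is taken from the matched header.
SENSOR_GLUCOSE_ALIASES = (
    "Sensor Glucose (mg/dL)",
    "Sensor Glucose (mmol/L)",
    "Glucose Sensor (mg/dL)",
    "Glucose Sensor (mmol/L)",
    "Sensor Glucose",
)

TIMESTAMP_ALIASES = ("Timestamp", "DateTime", "Date Time")


def _parse_timestamps(raw: pd.Series, dayfirst: bool) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", dayfirst=dayfirst)
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise InputFormatError(
            f"unparseable timestamp {raw.iloc[bad]!r} in data row {bad + 1}"
        )
    return parsed


def _series_from_frame(
    timestamps: pd.Series,
    glucose_raw: pd.Series,
    unit: Unit,
    patient_id: Optional[str],
) -> GlucoseSeries:
    glucose = pd.to_numeric(glucose_raw, errors="coerce")
    nonempty = glucose_raw.notna() & (glucose_raw.astype(str).str.strip() != "")
    bad = nonempty & glucose.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputFormatError(
            f"non-numeric glucose value {glucose_raw.iloc[row]!r} in data row {row + 1}"
        )
    frame = pd.DataFrame({"t": timestamps, "g": glucose}).dropna(subset=["g"])
    if frame.empty:
        raise InputFormatError("no glucose rows in input")
    frame = frame.sort_values("t", kind="stable")
    dup = frame.duplicated(subset="t", keep=False)
    if dup.any():
        conflicting = frame[dup].groupby("t")["g"].nunique()
        if (conflicting > 1).any():
            t = conflicting[conflicting > 1].index[0]
            raise InputFormatError(
                f"conflicting duplicate glucose values at timestamp {t}"
            )
        frame = frame.drop_duplicates(subset="t", keep="first")
    data = pd.Series(frame["g"].to_numpy(dtype=float), index=pd.DatetimeIndex(frame["t"]))
    return GlucoseSeries(data=data, unit=Unit(unit), patient_id=patient_id)


def read_generic_csv(
    path,
    timestamp_column: str,
    glucose_column: str,
    unit: Unit = Unit.MG_DL,
    *,
    dayfirst: bool = False,
    patient_id: Optional[str] = None,
) -> GlucoseSeries:
    """Read a two-column (timestamp, glucose) delimited table.

    Timestamps may be ISO-8601 or ``DD/MM/YYYY HH:MM`` (set ``dayfirst``).
    Rows with empty glucose cells are dropped; out-of-order rows are sorted;
    duplicate timestamps with identical glucose are deduplicated, with
    conflicting values an error.
    """
    table = pd.read_csv(path, dtype=str)
    for column in (timestamp_column, glucose_column):
        if column not in table.columns:
            raise ConfigError(
                f"column {column!r} not found in {path} "
                f"(available: {list(table.columns)})"
            )
    timestamps = _parse_timestamps(table[timestamp_column], dayfirst)
    return _series_from_frame(
        timestamps, table[glucose_column], Unit(unit), patient_id
    )


def _find_header_row(path) -> int:
    """Row index of the header line in a possibly-preambled export."""
    with open(path, newline="") as fh:
        for i, line in enumerate(fh):
            if any(alias in line for alias in SENSOR_GLUCOSE_ALIASES) or (
                "Timestamp" in line and "Glucose" in line
            ):
                return i
    return 0


def read_carelink_export(
    path, *, dayfirst: bool = False, patient_id: Optional[str] = None
) -> GlucoseSeries:
    """Read a CareLink-style CSV re-export.

    The sensor-glucose column is located via :data:`SENSOR_GLUCOSE_ALIASES`
    (unit inferred from the header); the timestamp comes from a
    ``Timestamp``-like column or a ``Date`` + ``Time`` pair.  Rows without a
    sensor value (calibration entries, alarms) are skipped.  Unknown layouts
    should go through :func:`read_generic_csv` with explicit column names.
    """
    header_row = _find_header_row(path)
    table = pd.read_csv(path, skiprows=header_row, dtype=str)
    table.columns = [str(c).strip() for c in table.columns]

    sensor_col = next(
        (a for a in SENSOR_GLUCOSE_ALIASES if a in table.columns), None
    )
    if sensor_col is None:
        raise InputFormatError(
            f"no sensor glucose column recognized in {path}; "
            f"detected headers: {list(table.columns)}"
        )
    unit = Unit.MMOL_L if "mmol" in sensor_col.lower() else Unit.MG_DL

    ts_col = next((a for a in TIMESTAMP_ALIASES if a in table.columns), None)
    if ts_col is not None:
        raw_ts = table[ts_col]
    elif "Date" in table.columns and "Time" in table.columns:
        raw_ts = table["Date"].str.strip() + " " + table["Time"].str.strip()
    else:
        raise InputFormatError(
            f"no timestamp column recognized in {path}; "
            f"detected headers: {list(table.columns)}"
        )

    sensor = table[sensor_col]
    has_value = sensor.notna() & (sensor.astype(str).str.strip() != "")
    if not has_value.any():
        raise InputFormatError(f"no sensor glucose rows in {path}")
    table = table[has_value]
    timestamps = _parse_timestamps(raw_ts[has_value], dayfirst)
    return _series_from_frame(timestamps, table[sensor_col], unit, patient_id)


def convert_units(series: GlucoseSeries, target: Unit) -> GlucoseSeries:
    """Convert a series to ``target`` unit (18.0182 mg/dL per mmol/L).

    Identity when the unit already matches; exact bijection up to floating
    precision otherwise.
    """
    try:
        target = Unit(target)
    except ValueError as exc:
        raise ConfigError(f"unknown unit: {target!r}") from exc
    return series.to_unit(target)


def write_generic_csv(series: GlucoseSeries, path) -> None:
    """Write a series as a generic two-column CSV (timestamp, glucose)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp", "glucose"])
        for t, g in series.data.items():
            writer.writerow([t.isoformat(), repr(float(g))])


def write_report(report: VariabilityReport, path, format: str = "json") -> None:
    """Write a report as JSON (documented schema) or a single-row CSV."""
    if format == "json":
        report.to_json(path)
    elif format == "csv":
        report.to_csv(path)
    else:
        raise ConfigError(f"unknown report format: {format!r}")
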