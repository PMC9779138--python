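"""Ingestion and preparation of hourly air-monitoring data.

This module turns raw hourly monitoring tables (pollutant concentrations plus
meteorology) into complete-case modeling tables with numeric time features,
and assigns reproducible train/validation/test splits.

Variables
---------
Concentrations: ``O3``, ``NO``, ``NO2``, ``SO2``, ``PM10`` (µg/m³) and ``CO``
(mg/m³).  Meteorology: ``WS`` (m/s), ``T`` (°C), ``I`` (W/m²), ``RH`` (%).
Time features: ``D`` (numeric day) and ``H`` (numeric hour), computed by
:func:`encode_time`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = [
    "CONCENTRATION_VARIABLES",
    "METEO_VARIABLES",
    "TIME_VARIABLES",
    "KNOWN_VARIABLES",
    "MonitoringSeries",
    "VariableSpec",
    "CaseTable",
    "SplitAssignment",
    "read_monitoring_csv",
    "encode_time",
    "expected_case_count",
    "build_case_table",
    "split_train_valid_test",
    "apportion",
]

CONCENTRATION_VARIABLES = ("O3", "NO", "NO2", "SO2", "CO", "PM10")
METEO_VARIABLES = ("WS", "T", "I", "RH")
TIME_VARIABLES = ("D", "H")
KNOWN_VARIABLES = CONCENTRATION_VARIABLES + METEO_VARIABLES

TRAIN, VALID, TEST = "train", "valid", "test"
SPLIT_LABELS = (TRAIN, VALID, TEST)


@dataclass
class MonitoringSeries:
    """An hourly multivariate monitoring record, possibly with gaps.

    ``data`` is indexed by a strictly increasing hourly ``DatetimeIndex`` with
    no duplicates; every column is one of :data:`KNOWN_VARIABLES`.  Missing
    measurements are ``NaN``.  Present concentrations must be non-negative and
    relative humidity must lie in [0, 100].
    """

    station_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise SchemaError("monitoring data must be indexed by timestamps")
        if idx.has_duplicates:
            first = idx[idx.duplicated()][0]
            raise SchemaError(f"duplicate timestamp: {first}")
        if len(idx) > 1:
            deltas = np.diff(idx.view("i8"))
            if not np.all(deltas == 3_600_000_000_000):
                pos = int(np.argmax(deltas != 3_600_000_000_000))
                raise SchemaError(
                    f"timestamps are not on a 1 h grid near {idx[pos]}"
                )
        unknown = set(self.data.columns) - set(KNOWN_VARIABLES)
        if unknown:
            raise SchemaError(f"unknown variable(s): {sorted(unknown)}")
        for var in self.data.columns:
            col = self.data[var].to_numpy(dtype=float)
            present = col[~np.isnan(col)]
            if var in CONCENTRATION_VARIABLES and np.any(present < 0):
                raise SchemaError(f"negative {var} concentration present")
            if var == "RH" and (np.any(present < 0) or np.any(present > 100)):
                raise SchemaError("RH outside [0, 100]")


@dataclass(frozen=True)
class VariableSpec:
    """Target variable and ordered predictor list for one regression setup.

    Predictors may include the numeric time features ``D`` and ``H``; all
    other names must be measured variables.
    """

    target: str
    predictors: tuple[str, ...]

    def __init__(self, target: str, predictors: Sequence[str]):
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "predictors", tuple(predictors))
        if not self.predictors:
            raise SchemaError("predictor list is empty")
        if self.target in self.predictors:
            raise SchemaError(f"target {self.target!r} also listed as predictor")
        if self.target not in KNOWN_VARIABLES:
            raise SchemaError(f"unknown target variable {self.target!r}")
        for name in self.predictors:
            if name not in KNOWN_VARIABLES + TIME_VARIABLES:
                raise SchemaError(f"unknown predictor variable {name!r}")

    @property
    def measured_predictors(self) -> tuple[str, ...]:
        return tuple(p for p in self.predictors if p not in TIME_VARIABLES)


@dataclass
class CaseTable:
    """Complete-case modeling table for one target variable.

    ``frame`` holds one row per fully observed hour, with columns in the fixed
    order ``spec.predictors + (target,)``.  ``provenance`` records where the
    cases came from (station, target, time-encoding convention, ...).
    """

    frame: pd.DataFrame
    target: str
    predictors: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = list(self.predictors) + [self.target]
        if list(self.frame.columns) != expected:
            raise SchemaError(
                f"case table columns {list(self.frame.columns)} != {expected}"
            )
        if self.frame.isna().any().any():
            raise SchemaError("case table contains missing values")
        if len(self.frame) < 1:
            raise SchemaError("case table is empty")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.predictors)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.target].to_numpy(dtype=float)

    def subset(self, indices: np.ndarray, note: str | None = None) -> "CaseTable":
        prov = dict(self.provenance)
        if note:
            prov["subset"] = note
        return CaseTable(
            frame=self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
            target=self.target,
            predictors=self.predictors,
            provenance=prov,
        )


@dataclass(frozen=True)
class SplitAssignment:
    """Per-case train/valid/test labels drawn at a fixed seed."""

    labels: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    @property
    def counts(self) -> tuple[int, int, int]:
        return tuple(int(np.sum(self.labels == lab)) for lab in SPLIT_LABELS)


def apportion(n: int, fractions: Sequence[float]) -> tuple[int, ...]:
    """Split ``n`` items into integer counts by largest-remainder rounding.

    Ties in the fractional parts are broken toward earlier positions.
    """
    quotas = [n * f for f in fractions]
    counts = [math.floor(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return tuple(counts)


def read_monitoring_csv(
    path,
    schema: Mapping[str, str],
    station_id: str = "",
    timestamp_col: str = "timestamp",
) -> MonitoringSeries:
    """Read an hourly monitoring CSV into a validated :class:`MonitoringSeries`.

    ``schema`` maps variable names (subset of :data:`KNOWN_VARIABLES`) to CSV
    column names.  Non-numeric or empty cells become missing; negative
    concentration cells are rejected (made missing) rather than clipped.
    Hours absent from the file are inserted as all-missing rows so that the
    1 h grid invariant holds.

    Raises
    ------
    SchemaError
        On duplicate timestamps (naming the first duplicate) or on a schema
        entry that is not a known variable name.
    """
    unknown = set(schema) - set(KNOWN_VARIABLES)
    if unknown:
        raise SchemaError(f"unknown variable name(s) in schema: {sorted(unknown)}")
    raw = pd.read_csv(path)
    if timestamp_col not in raw.columns:
        raise SchemaError(f"timestamp column {timestamp_col!r} not found")
    ts = pd.to_datetime(raw[timestamp_col], format="ISO8601")
    if ts.duplicated().any():
        first = ts[ts.duplicated()].iloc[0]
        raise SchemaError(f"duplicate timestamp: {first}")

    data = pd.DataFrame(index=pd.DatetimeIndex(ts, name="timestamp"))
    for var, col in schema.items():
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} for variable {var} not in file")
        vals = pd.to_numeric(raw[col], errors="coerce").to_numpy(dtype=float)
        if var in CONCENTRATION_VARIABLES:
            vals = np.where(vals < 0, np.nan, vals)
        data[var] = vals
    data = data.sort_index()
    full = pd.date_range(data.index[0], data.index[-1], freq="h")
    data = data.reindex(full)
    data.index.name = "timestamp"
    return MonitoringSeries(station_id=station_id, data=data)


def _day_of_year(ts: pd.Timestamp | datetime) -> int:
    return pd.Timestamp(ts).dayofyear


def encode_time(timestamp, convention: str = "linear") -> tuple[float, float]:
    """Encode a timestamp into numeric day (D) and hour (H) features.

    ``linear``: D is day-of-year (1–366), H is hour-of-day (0–23).
    ``cosine``: both are mapped through a cosine onto [−1, 1]; D peaks at the
    middle of the year and H at midday, so consecutive hours (including the
    23→00 wrap) are always close in feature space.
    """
    ts = pd.Timestamp(timestamp)
    doy, hour = ts.dayofyear, ts.hour
    if convention == "linear":
        return float(doy), float(hour)
    if convention == "cosine":
        d = -math.cos(2.0 * math.pi * (doy - 1) / 365.25)
        h = -math.cos(2.0 * math.pi * hour / 24.0)
        return d, h
    raise ValueError(f"unknown time-encoding convention {convention!r}")


def _encode_index(idx: pd.DatetimeIndex, convention: str) -> tuple[np.ndarray, np.ndarray]:
    doy = idx.dayofyear.to_numpy(dtype=float)
    hour = idx.hour.to_numpy(dtype=float)
    if convention == "linear":
        return doy, hour
    if convention == "cosine":
        return (
            -np.cos(2.0 * np.pi * (doy - 1) / 365.25),
            -np.cos(2.0 * np.pi * hour / 24.0),
        )
    raise ValueError(f"unknown time-encoding convention {convention!r}")


def expected_case_count(start_date, end_date) -> int:
    """Number of whole hours in the closed date range [start_date, end_date].

    Example: 2011-01-01 through 2016-12-31 spans 52,608 hourly cases.
    """
    start = pd.Timestamp(start_date).date() if not isinstance(start_date, date) else start_date
    end = pd.Timestamp(end_date).date() if not isinstance(end_date, date) else end_date
    if isinstance(start, datetime):
        start = start.date()
    if isinstance(end, datetime):
        end = end.date()
    if start > end:
        raise ValueError("start date after end date")
    return ((end - start).days + 1) * 24


def build_case_table(
    series: MonitoringSeries, spec: VariableSpec, convention: str = "linear"
) -> CaseTable:
    """Assemble the complete-case table for one target model.

    Keeps exactly the hours at which the target and every measured predictor
    are present; rows stay in chronological order.  D and H are computed from
    the timestamp by the chosen convention, which is recorded in provenance.
    """
    required = set(spec.measured_predictors) | {spec.target}
    missing_vars = required - set(series.variables)
    if missing_vars:
        raise SchemaError(
            f"series lacks required variable(s): {sorted(missing_vars)}"
        )
    sub = series.data[sorted(required)]
    complete = ~sub.isna().any(axis=1)
    if not complete.any():
        raise SchemaError("no complete cases survive filtering")
    kept = series.data.loc[complete]
    d_vals, h_vals = _encode_index(kept.index, convention)

    frame = pd.DataFrame(index=kept.index)
    for name in spec.predictors:
        if name == "D":
            frame[name] = d_vals
        elif name == "H":
            frame[name] = h_vals
        else:
            frame[name] = kept[name].to_numpy(dtype=float)
    frame[spec.target] = kept[spec.target].to_numpy(dtype=float)
    frame = frame.reset_index(drop=True)
    return CaseTable(
        frame=frame,
        target=spec.target,
        predictors=spec.predictors,
        provenance={
            "station_id": series.station_id,
            "target": spec.target,
            "time_encoding": convention,
            "n_source_hours": len(series),
        },
    )


def split_train_valid_test(
    table: CaseTable,
    seed: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SplitAssignment:
    """Assign cases at random to train/valid/test in the given proportions.

    Counts follow largest-remainder apportionment (exact when n is a multiple
    of 20, within ±1 otherwise) and the assignment is a seeded permutation, so
    identical inputs always give identical labels.
    """
    n = table.n
    if n < 7:
        raise ValueError(f"need at least 7 cases to populate three splits, got {n}")
    counts = apportion(n, fractions)
    labels = np.repeat(np.array(SPLIT_LABELS, dtype=object), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return SplitAssignment(labels=labels, fractions=tuple(fractions), seed=seed)
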