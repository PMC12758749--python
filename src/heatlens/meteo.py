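"""Daily-summary meteorology: GSOD-dialect parsing and regional aggregation.

The input dialect is a CSV with columns STATION, DATE (ISO-8601) and MAX
(daily maximum temperature in °F), with 9999.9 as the missing-value sentinel
— the convention of NOAA's Global Summary of the Day archive. Temperatures
are converted to °C and station values are averaged (unweighted) within each
region per day; monthly means average the available daily values.
"""
from __future__ import annotations

import datetime as dt
import logging
import math
from collections.abc import Iterable, Mapping

import pandas as pd

from .records import RegionDayTemp, StationRecord

log = logging.getLogger(__name__)

#: Sentinel used for a missing daily maximum in the GSOD dialect.
MISSING_SENTINEL = 9999.9

_REQUIRED_COLUMNS = ("STATION", "DATE", "MAX")


def f_to_c(t: float | None) -> float | None:
    """Convert °F to °C; missing (None/NaN) passes through unchanged."""
    if t is None:
        return None
    if isinstance(t, float) and math.isnan(t):
        return t
    return (t - 32.0) * 5.0 / 9.0


def c_to_f(t: float | None) -> float | None:
    """Convert °C to °F; missing (None/NaN) passes through unchanged."""
    if t is None:
        return None
    if isinstance(t, float) and math.isnan(t):
        return t
    return t * 9.0 / 5.0 + 32.0


def read_gsod(path) -> list[StationRecord]:
    """Parse a GSOD-dialect CSV into station-day records.

    The sentinel 9999.9 is mapped to missing. Rows with an unparseable date
    or temperature are rejected and their (1-based, header-excluded) row
    numbers logged at WARNING.

    Raises
    ------
    ValueError
        If a required column (STATION, DATE, MAX) is absent.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"GSOD file {path!r} is missing required column {col!r}")

    records: list[StationRecord] = []
    rejected: list[int] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        station = str(getattr(row, "STATION")).strip()
        try:
            date = dt.date.fromisoformat(str(getattr(row, "DATE")).strip())
            raw_max = str(getattr(row, "MAX")).strip()
            tmax_f: float | None = float(raw_max)
        except ValueError:
            rejected.append(row_no)
            continue
        if not station:
            rejected.append(row_no)
            continue
        if abs(tmax_f - MISSING_SENTINEL) < 1e-6:
            tmax_f = None
        records.append(StationRecord(station=station, date=date, tmax_f=tmax_f))
    if rejected:
        log.warning("read_gsod: rejected %d malformed row(s): %s", len(rejected), rejected)
    return records


def region_daily_tmax(
    stations: Iterable[StationRecord],
    station_map: Mapping[str, str],
) -> list[RegionDayTemp]:
    """Aggregate station daily maxima to regional daily means in °C.

    Each region-day value is the unweighted mean over stations that reported
    (missing values excluded); region-days with no reporting station are
    omitted (count logged). Stations absent from ``station_map`` are an
    error — silent dropping would bias the regional mean.
    """
    stations = list(stations)
    unknown = sorted({s.station for s in stations} - set(station_map))
    if unknown:
        raise ValueError(f"stations absent from the station→region map: {unknown}")

    rows = [
        (station_map[s.station], s.date, f_to_c(s.tmax_f))
        for s in stations
    ]
    frame = pd.DataFrame(rows, columns=["region", "date", "tmax_c"])
    n_missing = int(frame["tmax_c"].isna().sum())
    frame = frame.dropna(subset=["tmax_c"])
    if n_missing:
        log.info("region_daily_tmax: %d missing station-day value(s) excluded", n_missing)

    out: list[RegionDayTemp] = []
    grouped = frame.groupby(["region", "date"], sort=True)["tmax_c"]
    agg = grouped.agg(["mean", "count", "min", "max"])
    for (region, date), row in agg.iterrows():
        # aggregation must stay inside the contributing extremes
        assert row["min"] - 1e-9 <= row["mean"] <= row["max"] + 1e-9
        out.append(
            RegionDayTemp(
                region=region,
                date=date,
                tmax_c=float(row["mean"]),
                n_stations=int(row["count"]),
            )
        )
    return out


def monthly_mean_tmax(region_days: Iterable[RegionDayTemp]) -> pd.DataFrame:
    """Mean of available daily maxima per region-month.

    Returns a DataFrame with columns ``region``, ``month`` ("YYYY-MM"),
    ``tmax_c`` and ``n_days`` (coverage count). Empty months are simply
    absent from the table.
    """
    rows = [
        (d.region, f"{d.date.year:04d}-{d.date.month:02d}", d.tmax_c)
        for d in region_days
    ]
    frame = pd.DataFrame(rows, columns=["region", "month", "tmax_c"])
    if frame.empty:
        return pd.DataFrame(columns=["region", "month", "tmax_c", "n_days"])
    agg = (
        frame.groupby(["region", "month"], sort=True)["tmax_c"]
        .agg(tmax_c="mean", n_days="count")
        .reset_index()
    )
    agg["n_days"] = agg["n_days"].astype(int)
    return agg


def write_gsod(records: Iterable[StationRecord], path) -> None:
    """Write station records in the GSOD dialect read by :func:`read_gsod`."""
    rows = []
    for r in records:
        tmax = MISSING_SENTINEL if r.tmax_f is None else r.tmax_f
        rows.append((r.station, r.date.isoformat(), f"{tmax:.4f}"))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)
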