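"""Daily meteorology tables and per-recording exposures.

A meteorology table has one row per (date, location) with the daily mean
ambient temperature Ta [degC], relative humidity [%], barometric pressure
[hPa] and local sunrise/sunset clock times. A Holter-style recording spans
two consecutive calendar days; its exposure averages Ta/humidity/pressure
over the two days and takes the sunset of day 1 (the evening actually spent
awake) and the sunrise of day 2 (the morning of awakening), each expressed
as minutes elapsed from its own day's midnight.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

METEO_COLUMNS = ["date", "location", "ta_mean", "humidity", "pressure", "sunrise", "sunset"]


class MeteoValidationError(ValueError):
    """A meteorology row violates a physical bound."""


@dataclass(frozen=True)
class MeteoExposure:
    """Per-recording meteorological covariates."""

    ta: float          # degC, 2-day mean
    humidity: float    # %, 2-day mean
    pressure: float    # hPa, 2-day mean
    sunset_elapsed: float   # minutes from midnight of the recording start day
    sunrise_elapsed: float  # minutes from midnight of the recording end day


def parse_clock(value: str | dt.time) -> dt.time:
    """Parse a local 'HH:MM' string into a time (pass times through)."""
    if isinstance(value, dt.time):
        return value
    try:
        hh, mm = str(value).strip().split(":")
        return dt.time(int(hh), int(mm))
    except Exception as exc:  # noqa: BLE001 - uniform parse error
        raise ValueError(f"invalid clock time {value!r}") from exc


def time_to_minutes(t: dt.time) -> int:
    """Minutes from midnight of the time's own day, in [0, 1440)."""
    return t.hour * 60 + t.minute


def clock_to_elapsed(clock: str | dt.time, day_index: int) -> int:
    """Clock time -> minutes elapsed from 0:00 of the recording start day.

    ``day_index`` is 1 for the start day and 2 for the following day, so the
    result lies in [0, 2880).
    """
    if day_index not in (1, 2):
        raise ValueError(f"day_index must be 1 or 2, got {day_index}")
    return 1440 * (day_index - 1) + time_to_minutes(parse_clock(clock))


def validate_meteo(table: pd.DataFrame) -> pd.DataFrame:
    """Validate bounds and normalize dtypes of a meteorology table."""
    missing = [c for c in METEO_COLUMNS if c not in table.columns]
    if missing:
        raise MeteoValidationError(f"missing meteorology columns: {missing}")
    out = table.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out["sunrise"] = out["sunrise"].map(parse_clock)
    out["sunset"] = out["sunset"].map(parse_clock)
    bad_h = ~out["humidity"].between(0, 100)
    if bad_h.any():
        raise MeteoValidationError(
            f"humidity outside [0, 100] at rows {list(out.index[bad_h][:5])}"
        )
    bad_p = ~out["pressure"].between(900, 1100)
    if bad_p.any():
        raise MeteoValidationError(
            f"pressure outside [900, 1100] hPa at rows {list(out.index[bad_p][:5])}"
        )
    rise = out["sunrise"].map(time_to_minutes)
    sett = out["sunset"].map(time_to_minutes)
    if (rise >= sett).any():
        raise MeteoValidationError("sunrise must precede sunset")
    return out


def read_meteo_csv(path) -> pd.DataFrame:
    """Read and validate a daily meteorology CSV.

    Expected header: ``date,location,ta_mean,humidity,pressure,sunrise,sunset``
    with dates as YYYY-MM-DD and clock times as HH:MM.
    """
    table = pd.read_csv(path)
    if table.empty:
        logger.warning("meteorology file %s is empty", path)
        return pd.DataFrame(columns=METEO_COLUMNS)
    try:
        return validate_meteo(table)
    except MeteoValidationError:
        raise
    except Exception as exc:
        raise MeteoValidationError(f"malformed meteorology file {path}: {exc}") from exc


def write_meteo_csv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["sunrise"] = out["sunrise"].map(lambda t: f"{t.hour:02d}:{t.minute:02d}")
    out["sunset"] = out["sunset"].map(lambda t: f"{t.hour:02d}:{t.minute:02d}")
    out.to_csv(path, index=False)


def average_recording_exposure(day1: pd.Series, day2: pd.Series) -> MeteoExposure:
    """Combine two consecutive daily rows into one recording exposure.

    Ta/humidity/pressure are arithmetic 2-day means; sunset comes from day 1
    and sunrise from day 2, each as minutes from its own day's midnight.
    """
    d1, d2 = day1["date"], day2["date"]
    if d2 - d1 != dt.timedelta(days=1):
        raise ValueError(f"recording days must be consecutive, got {d1} and {d2}")
    if day1["location"] != day2["location"]:
        raise ValueError("recording days must share a location")
    return MeteoExposure(
        ta=(day1["ta_mean"] + day2["ta_mean"]) / 2.0,
        humidity=(day1["humidity"] + day2["humidity"]) / 2.0,
        pressure=(day1["pressure"] + day2["pressure"]) / 2.0,
        sunset_elapsed=time_to_minutes(parse_clock(day1["sunset"])),
        sunrise_elapsed=time_to_minutes(parse_clock(day2["sunrise"])),
    )


def exposure_table(meteo: pd.DataFrame, start_dates: pd.Series, location: str | None = None) -> pd.DataFrame:
    """Vectorized exposures for many recordings starting on ``start_dates``.

    Returns a DataFrame aligned with ``start_dates`` with columns
    ta/humidity/pressure/sunset/sunrise (the regression covariates).
    """
    tab = meteo if location is None else meteo[meteo["location"] == location]
    tab = tab.set_index("date")
    dates = pd.Series(pd.to_datetime(start_dates).dt.date.values, index=start_dates.index)
    next_dates = dates + dt.timedelta(days=1)
    missing = [d for d in {*dates, *next_dates} if d not in tab.index]
    if missing:
        raise LookupError(f"no meteorology for dates {sorted(missing)[:5]} ...")
    d1 = tab.loc[dates.values]
    d2 = tab.loc[next_dates.values]
    return pd.DataFrame(
        {
            "ta": (d1["ta_mean"].values + d2["ta_mean"].values) / 2.0,
            "humidity": (d1["humidity"].values + d2["humidity"].values) / 2.0,
            "pressure": (d1["pressure"].values + d2["pressure"].values) / 2.0,
            "sunset": [time_to_minutes(t) for t in d1["sunset"]],
            "sunrise": [time_to_minutes(t) for t in d2["sunrise"]],
        },
        index=start_dates.index,
    )
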