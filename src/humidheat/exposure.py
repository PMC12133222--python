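"""Exceedance-day statistics: weather series → daily wet-bulb → counts.

The unit of analysis is the *exceedance day*: a day whose peak
daytime-window wet-bulb temperature is at or above a species threshold
(the comparison is closed, ≥). Counts are aggregated per season — either
calendar years or austral-summer windows (October–March, labelled by the
starting year) — and averaged over complete seasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .psychro import rh_from_absolute_humidity, wet_bulb_stull

__all__ = [
    "WeatherSeries",
    "ExposureSummary",
    "daily_peak_wet_bulb",
    "count_exceedance",
    "exceedance_days",
    "read_weather_csv",
    "DEFAULT_DAYTIME_WINDOW",
]

logger = logging.getLogger(__name__)

DEFAULT_DAYTIME_WINDOW = (6, 18)

SEASONS = ("calendar_year", "oct_mar_summer")

# Months in each season window; oct_mar seasons are labelled by the
# year containing October.
_SEASON_MONTHS = {
    "calendar_year": tuple(range(1, 13)),
    "oct_mar_summer": (10, 11, 12, 1, 2, 3),
}


@dataclass
class WeatherSeries:
    """A time-stamped weather series for one site.

    ``data`` holds columns ``timestamp`` (datetime64), ``tair_c`` and
    ``rh_pct``; timestamps strictly increasing. ``cadence`` is
    ``"daily_max"`` (one row per day, air temperature is the daily
    maximum, humidity is the value supplied for that day — the file's
    contract, no coincident-hour reconstruction) or ``"hourly"``.
    """

    data: pd.DataFrame
    cadence: str = "daily_max"
    site: str = "site"
    lat: float | None = None
    lon: float | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.cadence not in ("daily_max", "hourly"):
            raise ValueError("cadence must be 'daily_max' or 'hourly'")
        required = {"timestamp", "tair_c", "rh_pct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"weather series missing columns: {sorted(missing)}")
        ts = pd.to_datetime(self.data["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        rh = self.data["rh_pct"].to_numpy(float)
        t = self.data["tair_c"].to_numpy(float)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(rh))):
            raise ValueError("non-finite weather values; drop them on read")
        if np.any(rh <= 0) or np.any(rh > 100):
            raise ValueError("rh_pct must lie in (0, 100]")
        self.data = self.data.assign(timestamp=ts).reset_index(drop=True)

    def with_provenance(self, note: str) -> "WeatherSeries":
        joined = f"{self.provenance}; {note}" if self.provenance else note
        return replace(self, data=self.data.copy(), provenance=joined)


@dataclass(frozen=True)
class ExposureSummary:
    """Exceedance days per season and their mean.

    ``per_year`` maps season label (the starting year of the window) to
    the number of days with wet-bulb ≥ threshold. ``mean_days_per_year``
    is the arithmetic mean over the seasons retained (complete seasons
    only unless partial ones were requested).
    """

    threshold: float
    season: str
    daytime_window: tuple[int, int]
    per_year: dict[int, int]
    mean_days_per_year: float
    n_years: int
    n_partial_excluded: int = 0
    dropped_days: int = 0

    def as_dict(self) -> dict:
        return {
            "threshold_c": self.threshold,
            "season": self.season,
            "daytime_window": list(self.daytime_window),
            "per_year": {str(k): v for k, v in self.per_year.items()},
            "mean_days_per_year": self.mean_days_per_year,
            "n_years": self.n_years,
            "n_partial_excluded": self.n_partial_excluded,
            "dropped_days": self.dropped_days,
        }


def read_weather_csv(
    path: str | Path,
    cadence: str = "daily_max",
    site: str = "site",
) -> WeatherSeries:
    """Read a weather CSV with columns timestamp, tair_c and rh_pct or ah_gm3.

    If humidity is supplied as absolute humidity (``ah_gm3``), relative
    humidity is derived at each row's air temperature (clipped at
    saturation, with a log message if clipping occurred). Rows with
    non-finite values are dropped and counted.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "rh_pct" not in df.columns:
        if "ah_gm3" not in df.columns:
            raise ValueError("weather CSV needs an rh_pct or ah_gm3 column")
        rh = rh_from_absolute_humidity(
            df["tair_c"].to_numpy(float), df["ah_gm3"].to_numpy(float), clip=True
        )
        n_clip = int(np.sum(rh >= 100.0 - 1e-12))
        if n_clip:
            logger.info("clipped %d supersaturated rows to rh = 100%%", n_clip)
        df = df.assign(rh_pct=rh)
    n0 = len(df)
    df = df.dropna(subset=["timestamp", "tair_c", "rh_pct"])
    df = df[np.isfinite(df["tair_c"]) & np.isfinite(df["rh_pct"])]
    if len(df) < n0:
        logger.info("dropped %d non-finite weather rows", n0 - len(df))
    return WeatherSeries(
        data=df[["timestamp", "tair_c", "rh_pct"]],
        cadence=cadence,
        site=site,
        provenance=f"read from {path}",
    )


def daily_peak_wet_bulb(
    series: WeatherSeries,
    window: tuple[int, int] = DEFAULT_DAYTIME_WINDOW,
) -> pd.DataFrame:
    """Daily peak wet-bulb temperature, one row per day.

    Hourly cadence: the Stull wet-bulb is computed for every record whose
    local hour lies in ``[window[0], window[1])`` and the daily maximum
    taken; days with no daytime records are dropped (counted in the
    ``dropped_days`` attribute of the result's ``attrs``). Daily cadence:
    the wet-bulb of each day's (t_air, rh) pair.

    Returns a DataFrame with columns ``date`` and ``tw_c``.
    """
    df = series.data
    if series.cadence == "hourly":
        hours = df["timestamp"].dt.hour
        day = df.loc[(hours >= window[0]) & (hours < window[1])].copy()
        all_days = df["timestamp"].dt.normalize().nunique()
        if day.empty:
            raise ValueError("no records inside the daytime window")
        day["tw_c"] = wet_bulb_stull(
            day["tair_c"].to_numpy(float), day["rh_pct"].to_numpy(float)
        )
        out = (
            day.groupby(day["timestamp"].dt.normalize())["tw_c"]
            .max()
            .rename_axis("date")
            .reset_index()
        )
        dropped = all_days - len(out)
        if dropped:
            logger.info("dropped %d days with no daytime records", dropped)
    else:
        out = pd.DataFrame(
            {
                "date": df["timestamp"].dt.normalize(),
                "tw_c": wet_bulb_stull(
                    df["tair_c"].to_numpy(float), df["rh_pct"].to_numpy(float)
                ),
            }
        )
        dropped = 0
    out.attrs["dropped_days"] = int(dropped)
    return out


def _season_label(dates: pd.Series, season: str) -> pd.Series:
    """Season label (starting year) for each date; NaN outside the window."""
    months = _SEASON_MONTHS[season]
    year = dates.dt.year
    if season == "calendar_year":
        return year.astype(float)
    lab = year.where(dates.dt.month >= 10, year - 1).astype(float)
    return lab.where(dates.dt.month.isin(months))


def _complete_seasons(daily: pd.DataFrame, season: str) -> pd.Series:
    """Boolean by season label: does the season cover all its months?"""
    months_needed = set(_SEASON_MONTHS[season])
    present = daily.groupby("season_label")["date"].apply(
        lambda d: set(d.dt.month.unique()) >= months_needed
    )
    return present


def count_exceedance(
    daily_tw: pd.DataFrame,
    threshold: float,
    season: str = "oct_mar_summer",
    include_partial: bool = False,
) -> ExposureSummary:
    """Count days with wet-bulb ≥ threshold per season and average.

    A day counts iff ``tw_c >= threshold`` (closed comparison). Seasons
    not covering every month of their window are excluded from the mean
    by default (``include_partial=True`` retains them).
    """
    if season not in SEASONS:
        raise ValueError(f"season must be one of {SEASONS}")
    daily = daily_tw.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    daily["season_label"] = _season_label(daily["date"], season)
    daily = daily.dropna(subset=["season_label"])
    if daily.empty:
        raise ValueError("series does not intersect the requested season window")
    complete = _complete_seasons(daily, season)
    counts = (
        daily.groupby("season_label")["tw_c"]
        .apply(lambda tw: int(np.sum(tw.to_numpy() >= threshold)))
    )
    if not include_partial:
        kept = counts[complete.reindex(counts.index, fill_value=False)]
    else:
        kept = counts
    n_excluded = len(counts) - len(kept)
    if kept.empty:
        raise ValueError(
            "no complete season in the series; pass include_partial=True "
            "to use partial seasons"
        )
    per_year = {int(k): int(v) for k, v in kept.items()}
    return ExposureSummary(
        threshold=float(threshold),
        season=season,
        daytime_window=DEFAULT_DAYTIME_WINDOW,
        per_year=per_year,
        mean_days_per_year=float(np.mean(list(per_year.values()))),
        n_years=len(per_year),
        n_partial_excluded=n_excluded,
        dropped_days=int(daily_tw.attrs.get("dropped_days", 0)),
    )


def exceedance_days(
    series: WeatherSeries,
    threshold: float,
    season: str = "oct_mar_summer",
    window: tuple[int, int] = DEFAULT_DAYTIME_WINDOW,
    include_partial: bool = False,
) -> ExposureSummary:
    """Convenience: daily peak wet-bulb then exceedance counting."""
    daily = daily_peak_wet_bulb(series, window=window)
    summary = count_exceedance(
        daily, threshold, season=season, include_partial=include_partial
    )
    return ExposureSummary(
        threshold=summary.threshold,
        season=summary.season,
        daytime_window=window,
        per_year=summary.per_year,
        mean_days_per_year=summary.mean_days_per_year,
        n_years=summary.n_years,
        n_partial_excluded=summary.n_partial_excluded,
        dropped_days=int(daily.attrs.get("dropped_days", 0)),
    )
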