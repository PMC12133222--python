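"""Shared fixtures: planted-wet-bulb weather fixtures built by inverting
the Stull formula, so expected exceedance counts are known integers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from humidheat import WeatherSeries, wet_bulb_stull

FIXTURE_RH = 60.0  # humidity used by the planted fixtures


def tair_for_tw(tw: float, rh: float = FIXTURE_RH) -> float:
    """Air temperature whose Stull wet-bulb at ``rh`` equals ``tw``."""
    return brentq(
        lambda t: wet_bulb_stull(t, rh, warn_envelope=False) - tw,
        -10.0, 55.0, xtol=1e-9,
    )


def planted_series(
    tw_background: float,
    planted: dict[int, list[float]],
    n_seasons: int = 3,
    start_year: int = 2000,
) -> WeatherSeries:
    """Daily series covering ``n_seasons`` complete Oct–Mar summers.

    Every day carries ``tw_background``; ``planted`` maps season index
    (0-based) to a list of wet-bulb values planted on consecutive
    January days of that season.
    """
    dates = pd.date_range(
        f"{start_year}-07-01", f"{start_year + n_seasons}-06-30", freq="D"
    )
    tw = np.full(len(dates), float(tw_background))
    for season_idx, values in planted.items():
        year = start_year + season_idx + 1  # January of that summer
        for k, val in enumerate(values):
            day = pd.Timestamp(year=year, month=1, day=5 + k)
            tw[dates.get_loc(day)] = val
    t_air = np.array([tair_for_tw(v) for v in tw])
    df = pd.DataFrame(
        {"timestamp": dates, "tair_c": t_air, "rh_pct": FIXTURE_RH}
    )
    return WeatherSeries(data=df, cadence="daily_max", site="planted")


@pytest.fixture(scope="session")
def three_per_season_series() -> WeatherSeries:
    """Exactly 3 days per season exceed a 25 °C threshold; 3 seasons."""
    planted = {i: [26.0, 26.5, 27.0] for i in range(3)}
    return planted_series(tw_background=22.0, planted=planted)


@pytest.fixture(scope="session")
def tiered_series() -> WeatherSeries:
    """One season with days planted at three wet-bulb tiers.

    Per season: 5 days at 27.5 °C, 3 days at 25.5 °C, 4 days at 23.5 °C,
    background 22.0 °C — so exceedance counts at thresholds 23/24/25/26/27
    are 12/8/8/5/5 exactly.
    """
    values = [27.5] * 5 + [25.5] * 3 + [23.5] * 4
    return planted_series(tw_background=22.0, planted={0: values}, n_seasons=1)
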