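"""Seeded generators for site weather series, weather grids and
thermal-endpoint tables with known ground truth.

The weather generator emulates a humid subtropical coastal climate:
daily maximum air temperature follows a seasonal sinusoid peaking in
austral mid-summer plus AR(1) Gaussian anomalies, and absolute humidity
follows correlated AR(1) anomalies around a fixed mean. Defaults match
the study region's reported summer climate (daily max 28.0 ± 1.9 °C,
absolute humidity 18.44 ± 0.65 g m⁻³). Relative humidity is derived
from (t, ah), so the temperature–humidity coupling that the
constant-RH vs constant-AH scenario contrast is sensitive to is present
by construction.

The endpoint-table generator plants a known species threshold: each
simulated bird's endpoint wet-bulb temperature is drawn from
Normal(true mean, true sd) and realised as a physiologically consistent
chamber state, so threshold estimation can be checked by parameter
recovery. Optional decoy records violate one of the two qualifying
criteria to exercise filtering.

All generators are pure functions of their parameters and seed;
per-generator substreams are derived from the single seed with fixed
offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import brentq
from shapely.geometry import box, mapping

from .endpoints import EndpointRecord
from .exposure import WeatherSeries
from .psychro import (
    absolute_humidity,
    rh_from_absolute_humidity,
    wet_bulb_stull,
)
from .spatial import WeatherGrid

__all__ = [
    "ClimateParams",
    "generate_site_series",
    "generate_grid",
    "generate_endpoint_table",
    "load_params",
]

logger = logging.getLogger(__name__)

# Substream offsets mixed into the seed so each generator has an
# independent, reproducible stream.
_STREAM_SITE = 101
_STREAM_GRID = 211
_STREAM_ENDPOINTS = 307


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic daily-weather process.

    ``mean_tmax``/``sd_tmax`` are the mean and SD of summer
    (October–March) daily maximum air temperature (°C);
    ``mean_ah``/``sd_ah`` the mean and SD of daily absolute humidity
    (g m⁻³); ``seasonal_amplitude`` the peak-to-trough range of the
    seasonal cycle (°C); ``ar1_rho`` the lag-1 autocorrelation of daily
    anomalies; ``tair_ah_corr`` the correlation between same-day
    temperature and humidity anomaly innovations.
    """

    mean_tmax: float = 28.0
    sd_tmax: float = 1.9
    mean_ah: float = 18.44
    sd_ah: float = 0.65
    seasonal_amplitude: float = 4.0
    ar1_rho: float = 0.6
    tair_ah_corr: float = 0.3
    n_years: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.sd_tmax < 0 or self.sd_ah < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if not (-1 <= self.tair_ah_corr <= 1):
            raise ValueError("tair_ah_corr must lie in [-1, 1]")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")


def _ar1(rng: np.random.Generator, n: int, rho: float, z0: np.ndarray) -> np.ndarray:
    """Standard-normal AR(1) path(s); z0 seeds the recursion (stationary)."""
    innov = rng.standard_normal((n,) + z0.shape)
    z = np.empty_like(innov)
    z[0] = z0
    s = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + s * innov[i]
    return z, innov


def _daily_dates(n_years: int, start_year: int = 2000) -> pd.DatetimeIndex:
    """Daily dates covering n_years complete October–March summers."""
    return pd.date_range(
        f"{start_year}-07-01", f"{start_year + n_years}-06-30", freq="D"
    )


def _seasonal_baseline(dates: pd.DatetimeIndex, params: ClimateParams) -> np.ndarray:
    """Sinusoidal climatology whose October–March mean is mean_tmax.

    Peak in mid-January (austral summer); amplitude is peak-to-trough.
    """
    doy = dates.dayofyear.to_numpy(float)
    phase = np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)
    a = params.seasonal_amplitude / 2.0
    summer = np.isin(dates.month, (10, 11, 12, 1, 2, 3))
    offset = params.mean_tmax - a * phase[summer].mean()
    return offset + a * phase


def _site_arrays(params: ClimateParams, rng: np.random.Generator):
    dates = _daily_dates(params.n_years)
    n = len(dates)
    z0 = rng.standard_normal(2)
    zt, innov_t = _ar1(rng, n, params.ar1_rho, z0[:1])
    # AH anomalies share the AR structure; innovations correlated with
    # the temperature innovations at tair_ah_corr.
    c = params.tair_ah_corr
    innov_a = c * innov_t + np.sqrt(1 - c**2) * rng.standard_normal((n, 1))
    za = np.empty_like(innov_a)
    za[0] = z0[1:]
    s = np.sqrt(1 - params.ar1_rho**2)
    for i in range(1, n):
        za[i] = params.ar1_rho * za[i - 1] + s * innov_a[i]
    t = _seasonal_baseline(dates, params) + params.sd_tmax * zt[:, 0]
    ah = np.maximum(params.mean_ah + params.sd_ah * za[:, 0], 0.05)
    rh = rh_from_absolute_humidity(t, ah, clip=True)
    n_clip = int(np.sum(rh >= 100.0 - 1e-12))
    if n_clip > 0.05 * n:
        logger.warning(
            "parameters force rh clipping on %d/%d days (> 5%%)", n_clip, n
        )
    rh = np.clip(rh, 0.1, 100.0)
    return dates, t, rh


def generate_site_series(params: ClimateParams) -> WeatherSeries:
    """Synthetic daily-maximum weather series for one site.

    The series covers ``n_years`` complete October–March summers
    (July to June calendar span) at daily cadence; deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng([params.seed, _STREAM_SITE])
    dates, t, rh = _site_arrays(params, rng)
    df = pd.DataFrame({"timestamp": dates, "tair_c": t, "rh_pct": rh})
    return WeatherSeries(
        data=df,
        cadence="daily_max",
        site="synthetic-site",
        provenance=f"synthetic AR(1) climate, seed={params.seed}",
    )


def generate_grid(
    params: ClimateParams,
    lat_range: tuple[float, float] = (-30.0, -26.0),
    lon_range: tuple[float, float] = (30.0, 34.0),
    nlat: int = 5,
    nlon: int = 4,
    gradient: float = 0.5,
) -> tuple[WeatherGrid, dict]:
    """Synthetic weather grid plus a notched GeoJSON range polygon.

    Each cell carries an independent site series whose mean temperature
    is shifted by ``gradient`` °C per degree of latitude away from the
    cold (most poleward) edge. The returned polygon is an L-shaped
    (rectangle-with-notch) range covering a known subset of cell
    centres, so mask rasterization is exercised; for the default 5×4
    grid it contains 8 of 20 centres (40%).
    """
    lats = np.linspace(lat_range[0], lat_range[1], nlat)
    lons = np.linspace(lon_range[0], lon_range[1], nlon)
    # Southern-hemisphere convention: the equatorward (max-lat) edge is warm.
    cold_edge = lats.min()
    tair = None
    rh = None
    for i, la in enumerate(lats):
        shift = gradient * (la - cold_edge)
        for j, _ in enumerate(lons):
            cell_params = ClimateParams(
                mean_tmax=params.mean_tmax + shift,
                sd_tmax=params.sd_tmax,
                mean_ah=params.mean_ah,
                sd_ah=params.sd_ah,
                seasonal_amplitude=params.seasonal_amplitude,
                ar1_rho=params.ar1_rho,
                tair_ah_corr=params.tair_ah_corr,
                n_years=params.n_years,
                seed=params.seed,
            )
            rng = np.random.default_rng([params.seed, _STREAM_GRID, i, j])
            dates, t_cell, rh_cell = _site_arrays(cell_params, rng)
            if tair is None:
                tair = np.empty((len(dates), nlat, nlon))
                rh = np.empty_like(tair)
            tair[:, i, j] = t_cell
            rh[:, i, j] = rh_cell
    ds = xr.Dataset(
        {
            "tair": (("time", "lat", "lon"), tair),
            "rh": (("time", "lat", "lon"), rh),
        },
        coords={"time": dates, "lat": lats, "lon": lons},
        attrs={"provenance": f"synthetic AR(1) climate grid, seed={params.seed}"},
    )
    polygon = _notched_polygon(lats, lons)
    return WeatherGrid(data=ds, cadence="daily_max"), polygon


def _notched_polygon(lats: np.ndarray, lons: np.ndarray) -> dict:
    """L-shaped polygon: 3 coldest lat rows minus a notch of the last
    two columns in rows 2–3. For a 5×4 grid: 12 − 4 = 8 centres in."""
    dla = (lats[1] - lats[0]) / 2.0 if len(lats) > 1 else 0.5
    dlo = (lons[1] - lons[0]) / 2.0 if len(lons) > 1 else 0.5
    nrows = min(3, len(lats))
    outer = box(
        lons[0] - dlo, lats[0] - dla, lons[-1] + dlo, lats[nrows - 1] + dla
    )
    if len(lats) >= 3 and len(lons) >= 3:
        notch = box(
            lons[-2] - dlo, lats[1] - dla, lons[-1] + dlo, lats[nrows - 1] + dla
        )
        geom = outer.difference(notch)
    else:
        geom = outer
    return {"type": "Feature", "properties": {}, "geometry": mapping(geom)}


def _solve_ah_for_wet_bulb(t_air: float, target_tw: float) -> float:
    """Chamber vapour density (g m⁻³) giving the target Stull wet-bulb
    at the given air temperature; bracketed in (0.05, saturation)."""
    ah_hi = absolute_humidity(t_air, 100.0) - 1e-9

    def f(ah):
        return wet_bulb_stull(
            t_air, rh_from_absolute_humidity(t_air, ah), warn_envelope=False
        ) - target_tw

    if f(0.05) * f(ah_hi) > 0:
        raise ArithmeticError(
            f"no chamber humidity gives wet-bulb {target_tw} °C at "
            f"t_air = {t_air} °C"
        )
    return brentq(f, 0.05, ah_hi, xtol=1e-6)


def generate_endpoint_table(
    n_birds: int = 8,
    true_twmax_mean: float = 31.7,
    true_twmax_sd: float = 1.0,
    treatment_ah: float = 25.0,
    decoy_fraction: float = 0.25,
    seed: int = 0,
) -> list[EndpointRecord]:
    """Endpoint records with a planted species threshold.

    Each qualifying bird's endpoint wet-bulb is drawn from
    Normal(``true_twmax_mean``, ``true_twmax_sd``); the chamber state is
    realised by drawing an endpoint air temperature near the species'
    heat tolerance limit and solving for the chamber vapour density that
    yields the drawn wet-bulb (so ``endpoint_wet_bulb`` recovers the
    draw to root-finder tolerance, and records stay inside
    physiological bounds). Body temperature sits a small positive offset
    above air temperature and locomotor impairment is set, so both
    qualifying criteria hold.

    ``decoy_fraction`` adds round(fraction × n_birds) non-qualifying
    records (body temperature held below air temperature, or no
    locomotor impairment) named ``decoy_*`` to exercise filtering.
    """
    rng = np.random.default_rng([seed, _STREAM_ENDPOINTS])
    records: list[EndpointRecord] = []
    for k in range(n_birds):
        tw = rng.normal(true_twmax_mean, true_twmax_sd)
        t_air = float(np.clip(rng.normal(44.5, 1.0), 40.0, 46.8))
        tw = float(np.clip(tw, 25.0, t_air - 0.5))
        ah = _solve_ah_for_wet_bulb(t_air, tw)
        t_b = min(t_air + float(rng.uniform(0.2, 1.0)), 47.9)
        records.append(
            EndpointRecord(
                bird_id=f"bird_{k + 1:02d}",
                sex="M" if rng.random() < 0.5 else "F",
                mass=float(rng.normal(600.0, 75.0)),
                treatment_ah=ah,
                t_air_end=t_air,
                t_b_end=t_b,
                locomotor_impaired=True,
                endpoint_reason="coordination_loss",
            )
        )
    n_decoys = int(round(decoy_fraction * n_birds))
    for k in range(n_decoys):
        t_air = float(np.clip(rng.normal(45.0, 1.0), 40.0, 47.0))
        if rng.random() < 0.5:
            # criterion 1 fails: bird still defends t_b below t_air
            t_b = t_air - float(rng.uniform(1.0, 3.0))
            impaired = True
            reason = "ewl_decline"
        else:
            # criterion 2 fails: no locomotor impairment observed
            t_b = min(t_air + float(rng.uniform(0.1, 0.6)), 47.9)
            impaired = False
            reason = "rmr_decline"
        records.append(
            EndpointRecord(
                bird_id=f"decoy_{k + 1:02d}",
                sex="unknown",
                mass=float(rng.normal(600.0, 75.0)),
                treatment_ah=treatment_ah,
                t_air_end=t_air,
                t_b_end=float(np.clip(t_b, 38.5, 47.9)),
                locomotor_impaired=impaired,
                endpoint_reason=reason,
            )
        )
    return records


def load_params(path: str | Path) -> ClimateParams:
    """Read ClimateParams from a flat ``key = value`` text file.

    Keys mirror the field names exactly; unknown keys are rejected.
    Lines starting with ``#`` and blank lines are ignored.
    """
    fields = ClimateParams.__dataclass_fields__
    kwargs: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"unknown ClimateParams field: {key!r}")
        typ = fields[key].type
        kwargs[key] = int(value) if typ == "int" else float(value)
    return ClimateParams(**kwargs)
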