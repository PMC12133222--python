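"""Range-wide gridded exposure, range-fraction summaries and a
parametric canopy-buffering transform.

Gridded weather is carried as an :class:`xarray.Dataset` with variables
``tair(time, lat, lon)`` and ``rh(time, lat, lon)`` (CF-style
coordinates). Exceedance counting is the same day-level rule as the
scalar path in :mod:`humidheat.exposure`, applied per cell; a species
range enters as a polygon rasterized onto the grid (a cell is in range
iff its centre lies inside the polygon).

The canopy transform is a deliberately simple stand-in for biophysical
microclimate models: inside vegetation the air is cooler by a fixed
offset, with humidity following one of two rules (vapour density
preserved — the common field observation — or relative humidity
preserved).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, shape

from .exposure import DEFAULT_DAYTIME_WINDOW, WeatherSeries, _SEASON_MONTHS
from .psychro import absolute_humidity, rh_from_absolute_humidity, wet_bulb_stull

__all__ = [
    "WeatherGrid",
    "GridExposure",
    "BufferingProfile",
    "grid_exposure",
    "fraction_range_exposed",
    "apply_buffering",
    "rasterize_range_mask",
    "cell_series",
    "sample_polygon_exposure",
    "read_weather_grid",
    "write_weather_grid",
]

logger = logging.getLogger(__name__)

HUMIDITY_RULES = ("preserve_absolute", "preserve_relative")


@dataclass
class WeatherGrid:
    """Gridded weather with an optional species-range mask.

    ``data`` must hold ``tair`` and ``rh`` over dims (time, lat, lon)
    with strictly monotone coordinates; ``cadence`` as in
    :class:`~humidheat.exposure.WeatherSeries`. ``mask`` is a boolean
    (lat, lon) array marking in-range cells.
    """

    data: xr.Dataset
    cadence: str = "daily_max"
    mask: xr.DataArray | None = None

    def __post_init__(self):
        for var in ("tair", "rh"):
            if var not in self.data:
                raise ValueError(f"grid dataset missing variable '{var}'")
            if self.data[var].dims != ("time", "lat", "lon"):
                raise ValueError(f"'{var}' must have dims (time, lat, lon)")
        for coord in ("lat", "lon"):
            v = self.data[coord].values
            d = np.diff(v)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{coord} coordinate must be strictly monotone")
        rh = self.data["rh"].values
        if np.any(rh <= 0) or np.any(rh > 100):
            raise ValueError("rh must lie in (0, 100]")
        if self.cadence not in ("daily_max", "hourly"):
            raise ValueError("cadence must be 'daily_max' or 'hourly'")
        if self.mask is not None and self.mask.shape != (
            self.data.sizes["lat"],
            self.data.sizes["lon"],
        ):
            raise ValueError("mask shape must be (lat, lon)")


@dataclass(frozen=True)
class GridExposure:
    """Per-cell mean exceedance days per year.

    ``mean_days`` is a (lat, lon) DataArray; cells outside the mask (when
    one is set) are NaN. ``n_years`` counts the complete seasons used.
    """

    mean_days: xr.DataArray
    threshold: float
    n_years: int
    season: str
    mask: xr.DataArray | None = None

    def as_dataset(self) -> xr.Dataset:
        ds = xr.Dataset({"mean_exceedance_days": self.mean_days})
        ds.attrs.update(
            threshold_c=self.threshold, n_years=self.n_years, season=self.season
        )
        return ds


@dataclass(frozen=True)
class BufferingProfile:
    """Parametric canopy microclimate: cooler, humidity by rule.

    ``t_offset`` (°C, ≥ 0) is subtracted from open-air temperature;
    ``humidity_rule`` is ``preserve_absolute`` (vapour density unchanged,
    rh recomputed and clipped at saturation) or ``preserve_relative``.
    """

    t_offset: float
    humidity_rule: str = "preserve_absolute"

    def __post_init__(self):
        if self.t_offset < 0:
            raise ValueError("t_offset must be >= 0 (canopy does not heat)")
        if self.humidity_rule not in HUMIDITY_RULES:
            raise ValueError(f"humidity_rule must be one of {HUMIDITY_RULES}")


def _as_geometry(polygon):
    """Accept a shapely geometry, GeoJSON mapping/str/path → shapely."""
    if hasattr(polygon, "geom_type"):
        return polygon
    if isinstance(polygon, (str, Path)):
        with open(polygon) as fh:
            polygon = json.load(fh)
    if isinstance(polygon, dict):
        if polygon.get("type") == "FeatureCollection":
            from shapely.ops import unary_union

            return unary_union([shape(f["geometry"]) for f in polygon["features"]])
        if polygon.get("type") == "Feature":
            return shape(polygon["geometry"])
        return shape(polygon)
    raise TypeError("polygon must be a shapely geometry, GeoJSON dict or path")


def rasterize_range_mask(grid: WeatherGrid | xr.Dataset, polygon) -> xr.DataArray:
    """Boolean (lat, lon) mask: cell centre inside the range polygon."""
    ds = grid.data if isinstance(grid, WeatherGrid) else grid
    geom = _as_geometry(polygon)
    lats = ds["lat"].values
    lons = ds["lon"].values
    mask = np.zeros((lats.size, lons.size), dtype=bool)
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            mask[i, j] = geom.contains(Point(float(lo), float(la)))
    return xr.DataArray(
        mask, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"), name="mask"
    )


def _daily_peak_tw(grid: WeatherGrid, window: tuple[int, int]) -> xr.DataArray:
    """Daily peak wet-bulb per cell: (time=day, lat, lon)."""
    ds = grid.data
    tw = xr.DataArray(
        wet_bulb_stull(ds["tair"].values, ds["rh"].values, warn_envelope=False),
        coords=ds["tair"].coords,
        dims=ds["tair"].dims,
        name="tw",
    )
    if grid.cadence == "hourly":
        hours = tw["time"].dt.hour
        tw = tw.isel(time=((hours >= window[0]) & (hours < window[1])).values)
        if tw.sizes["time"] == 0:
            raise ValueError("no records inside the daytime window")
        daily = tw.resample(time="1D").max()
        daily = daily.dropna("time", how="all")
    else:
        daily = tw
    return daily


def grid_exposure(
    grid: WeatherGrid,
    threshold: float,
    season: str = "calendar_year",
    window: tuple[int, int] = DEFAULT_DAYTIME_WINDOW,
) -> GridExposure:
    """Mean exceedance days per year for every grid cell.

    The day-level rule matches the scalar path exactly: a day counts iff
    its daytime-window peak wet-bulb is ≥ threshold; only seasons covering
    every month of their window contribute to the mean.
    """
    daily = _daily_peak_tw(grid, window)
    dates = pd.DatetimeIndex(daily["time"].values)
    months = dates.month
    years = dates.year
    if season == "calendar_year":
        labels = years.to_numpy()
        in_season = np.ones(len(dates), dtype=bool)
    elif season == "oct_mar_summer":
        labels = np.where(months >= 10, years, years - 1)
        in_season = np.isin(months, _SEASON_MONTHS["oct_mar_summer"])
    else:
        raise ValueError(f"unknown season '{season}'")
    labels = labels[in_season]
    if labels.size == 0:
        raise ValueError("grid does not intersect the requested season window")
    daily = daily.isel(time=in_season)
    months_in = pd.DatetimeIndex(daily["time"].values).month
    needed = set(_SEASON_MONTHS[season])
    complete = [
        lab
        for lab in np.unique(labels)
        if set(months_in[labels == lab]) >= needed
    ]
    if not complete:
        raise ValueError("no complete season in the grid's time axis")
    exceed = (daily >= threshold).values  # NaN days compare False
    counts = np.stack(
        [exceed[labels == lab].sum(axis=0) for lab in complete]
    )  # (season, lat, lon)
    mean_days = xr.DataArray(
        counts.mean(axis=0),
        coords={"lat": grid.data["lat"], "lon": grid.data["lon"]},
        dims=("lat", "lon"),
        name="mean_exceedance_days",
    )
    if grid.mask is not None:
        mean_days = mean_days.where(grid.mask)
    return GridExposure(
        mean_days=mean_days,
        threshold=float(threshold),
        n_years=len(complete),
        season=season,
        mask=grid.mask,
    )


def fraction_range_exposed(
    ge: GridExposure,
    min_days: float = 1.0,
    area_weighted: bool = False,
) -> float:
    """Percent of in-range cells with mean exceedance ≥ ``min_days``.

    With ``area_weighted=True`` cells are weighted by cos(latitude) to
    approximate equal-area weighting on a regular lat/lon grid.
    """
    if ge.mask is not None:
        in_range = ge.mask.values.astype(bool)
    else:
        in_range = np.isfinite(ge.mean_days.values)
    if not in_range.any():
        raise ValueError("range mask is empty")
    vals = ge.mean_days.values
    hot = in_range & (vals >= min_days)
    if area_weighted:
        w = np.cos(np.deg2rad(ge.mean_days["lat"].values))[:, None]
        w = np.broadcast_to(w, vals.shape)
        return 100.0 * w[hot].sum() / w[in_range].sum()
    return 100.0 * hot.sum() / in_range.sum()


def apply_buffering(obj, profile: BufferingProfile):
    """Apply the canopy transform to a series or grid (same type out).

    ``preserve_relative`` lowers every wet-bulb value (strictly, for a
    positive offset); ``preserve_absolute`` lowers temperature at fixed
    vapour density so rh rises and is clipped at saturation — the number
    of clipped records is recorded in the output's metadata.
    """
    if isinstance(obj, WeatherSeries):
        df = obj.data.copy()
        t = df["tair_c"].to_numpy(float)
        rh = df["rh_pct"].to_numpy(float)
        t_new, rh_new, n_clip = _buffer_arrays(t, rh, profile)
        df["tair_c"] = t_new
        df["rh_pct"] = rh_new
        out = replace(obj, data=df)
        return out.with_provenance(
            f"canopy buffering: -{profile.t_offset} C, {profile.humidity_rule}, "
            f"{n_clip} records clipped at saturation"
        )
    if isinstance(obj, WeatherGrid):
        t = obj.data["tair"].values
        rh = obj.data["rh"].values
        t_new, rh_new, n_clip = _buffer_arrays(t, rh, profile)
        ds = obj.data.copy()
        ds["tair"] = (ds["tair"].dims, t_new)
        ds["rh"] = (ds["rh"].dims, rh_new)
        ds.attrs["buffering"] = (
            f"-{profile.t_offset} C, {profile.humidity_rule}"
        )
        ds.attrs["buffering_clipped_records"] = int(n_clip)
        return WeatherGrid(data=ds, cadence=obj.cadence, mask=obj.mask)
    raise TypeError("apply_buffering expects a WeatherSeries or WeatherGrid")


def _buffer_arrays(t, rh, profile: BufferingProfile):
    t_new = t - profile.t_offset
    if profile.humidity_rule == "preserve_relative":
        return t_new, rh, 0
    ah = absolute_humidity(t, rh)
    rh_new = rh_from_absolute_humidity(t_new, ah, clip=True)
    n_clip = int(np.sum(rh_new >= 100.0 - 1e-12))
    if n_clip:
        logger.info("buffering clipped %d records at saturation", n_clip)
    return t_new, rh_new, n_clip


def cell_series(grid: WeatherGrid, ilat: int, ilon: int) -> WeatherSeries:
    """Extract one grid cell as a scalar WeatherSeries (oracle path)."""
    ds = grid.data.isel(lat=ilat, lon=ilon)
    df = pd.DataFrame(
        {
            "timestamp": pd.DatetimeIndex(ds["time"].values),
            "tair_c": ds["tair"].values,
            "rh_pct": ds["rh"].values,
        }
    )
    return WeatherSeries(
        data=df,
        cadence=grid.cadence,
        site=f"cell[{ilat},{ilon}]",
        lat=float(ds["lat"]),
        lon=float(ds["lon"]),
    )


def sample_polygon_exposure(
    ge: GridExposure,
    polygons,
    k: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Average exposure at ``k`` random points inside each polygon.

    Emulates a survey design in which a handful of representative forest
    areas are each probed at several random coordinates and the values
    averaged; points are mapped to the nearest grid cell. Returns one
    dict per polygon with the point values and their mean.
    """
    rng = np.random.default_rng(seed)
    geoms = polygons if isinstance(polygons, (list, tuple)) else [polygons]
    out = []
    for idx, poly in enumerate(geoms):
        geom = _as_geometry(poly)
        minx, miny, maxx, maxy = geom.bounds
        pts = []
        while len(pts) < k:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if geom.contains(Point(x, y)):
                pts.append((y, x))
        vals = [
            float(ge.mean_days.sel(lat=la, lon=lo, method="nearest"))
            for la, lo in pts
        ]
        out.append(
            {
                "polygon": idx,
                "points": pts,
                "values": vals,
                "mean_days": float(np.nanmean(vals)),
            }
        )
    return out


def read_weather_grid(path: str | Path, cadence: str = "daily_max") -> WeatherGrid:
    """Read a NetCDF grid with variables tair and rh (scipy engine)."""
    ds = xr.open_dataset(path, engine="scipy").load()
    ds = ds.assign_coords(time=pd.DatetimeIndex(ds.indexes["time"]))
    mask = None
    if "mask" in ds:
        mask = ds["mask"].astype(bool)
        ds = ds.drop_vars("mask")
    return WeatherGrid(data=ds, cadence=cadence, mask=mask)


def write_weather_grid(grid: WeatherGrid, path: str | Path) -> None:
    """Write a grid (and mask, if set) as NetCDF3 via the scipy engine."""
    ds = grid.data
    if grid.mask is not None:
        ds = ds.assign(mask=grid.mask.astype("int8"))
    ds.to_netcdf(path, engine="scipy")
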