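"""Gridded exceedance maps: planted cells, grid/scalar equivalence,
range-mask rasterization, range fractions and canopy buffering."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from shapely.geometry import box, mapping

from humidheat import (
    BufferingProfile,
    ClimateParams,
    GridExposure,
    WeatherGrid,
    apply_buffering,
    cell_series,
    exceedance_days,
    fraction_range_exposed,
    generate_grid,
    grid_exposure,
    rasterize_range_mask,
    sample_polygon_exposure,
)
from humidheat.spatial import read_weather_grid, write_weather_grid

from conftest import tair_for_tw


def planted_grid(exceed_days_per_cell: np.ndarray, threshold: float = 25.0) -> WeatherGrid:
    """Daily grid for one calendar year; cell (i, j) gets exactly
    ``exceed_days_per_cell[i, j]`` days above the threshold."""
    dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")
    nlat, nlon = exceed_days_per_cell.shape
    hot_t = tair_for_tw(threshold + 1.0)
    cold_t = tair_for_tw(threshold - 3.0)
    tair = np.full((len(dates), nlat, nlon), cold_t)
    for i in range(nlat):
        for j in range(nlon):
            k = int(exceed_days_per_cell[i, j])
            tair[100 : 100 + k, i, j] = hot_t
    ds = xr.Dataset(
        {
            "tair": (("time", "lat", "lon"), tair),
            "rh": (("time", "lat", "lon"), np.full_like(tair, 60.0)),
        },
        coords={
            "time": dates,
            "lat": np.linspace(-30, -28, nlat),
            "lon": np.linspace(30, 32, nlon),
        },
    )
    return WeatherGrid(data=ds, cadence="daily_max")


class TestGridExposure:
    def test_planted_cell_counts_exact(self):
        planted = np.array([[5, 0], [2, 12]])
        ge = grid_exposure(planted_grid(planted), 25.0, season="calendar_year")
        assert np.array_equal(ge.mean_days.values, planted.astype(float))
        assert ge.n_years == 1

    def test_grid_equals_scalar_path_per_cell(self):
        grid, _ = generate_grid(ClimateParams(n_years=2, seed=9), nlat=3, nlon=3)
        ge = grid_exposure(grid, 26.0, season="oct_mar_summer")
        for i in range(3):
            for j in range(3):
                scalar = exceedance_days(
                    cell_series(grid, i, j), 26.0, season="oct_mar_summer"
                )
                assert float(ge.mean_days[i, j]) == scalar.mean_days_per_year

    def test_masked_cells_are_sentinel(self):
        planted = np.array([[5, 0], [2, 12]])
        grid = planted_grid(planted)
        grid.mask = xr.DataArray(
            np.array([[True, True], [False, False]]),
            coords={"lat": grid.data["lat"], "lon": grid.data["lon"]},
            dims=("lat", "lon"),
        )
        ge = grid_exposure(grid, 25.0, season="calendar_year")
        assert np.isnan(ge.mean_days.values[1]).all()
        assert not np.isnan(ge.mean_days.values[0]).any()


class TestRangeMask:
    def test_notched_polygon_masks_forty_percent(self):
        grid, polygon = generate_grid(ClimateParams(n_years=1, seed=0))
        mask = rasterize_range_mask(grid, polygon)
        assert mask.values.sum() == 8
        assert mask.values.size == 20

    def test_fraction_range_exposed_planted_half(self):
        mean_days = xr.DataArray(
            np.array([[2.0, 3.0], [0.0, 0.5]]),
            coords={"lat": [-30.0, -29.0], "lon": [30.0, 31.0]},
            dims=("lat", "lon"),
        )
        ge = GridExposure(
            mean_days=mean_days, threshold=25.0, n_years=1, season="calendar_year"
        )
        assert fraction_range_exposed(ge, min_days=1.0) == 50.0
        assert fraction_range_exposed(ge, min_days=0.25) == 75.0

    def test_all_or_none_exposed(self):
        base = dict(threshold=25.0, n_years=1, season="calendar_year")
        coords = {"lat": [-30.0, -29.0], "lon": [30.0, 31.0]}
        hot = GridExposure(
            mean_days=xr.DataArray(
                np.full((2, 2), 9.0), coords=coords, dims=("lat", "lon")
            ),
            **base,
        )
        cold = GridExposure(
            mean_days=xr.DataArray(
                np.zeros((2, 2)), coords=coords, dims=("lat", "lon")
            ),
            **base,
        )
        assert fraction_range_exposed(hot) == 100.0
        assert fraction_range_exposed(cold) == 0.0

    def test_monotone_in_min_days(self):
        grid, polygon = generate_grid(ClimateParams(n_years=2, seed=4))
        grid.mask = rasterize_range_mask(grid, polygon)
        ge = grid_exposure(grid, 25.5, season="oct_mar_summer")
        fracs = [fraction_range_exposed(ge, m) for m in (0.5, 1.0, 2.0, 4.0)]
        assert fracs == sorted(fracs, reverse=True)

    def test_area_weighting_changes_weights_not_membership(self):
        mean_days = xr.DataArray(
            np.array([[2.0], [0.0]]),
            coords={"lat": [-60.0, 0.0], "lon": [30.0]},
            dims=("lat", "lon"),
        )
        ge = GridExposure(
            mean_days=mean_days, threshold=25.0, n_years=1, season="calendar_year"
        )
        unweighted = fraction_range_exposed(ge, 1.0)
        weighted = fraction_range_exposed(ge, 1.0, area_weighted=True)
        assert unweighted == 50.0
        # the exposed cell sits at 60° latitude → less than half the area
        assert weighted < unweighted

    def test_empty_mask_raises(self):
        mean_days = xr.DataArray(
            np.zeros((1, 1)), coords={"lat": [0.0], "lon": [0.0]}, dims=("lat", "lon")
        )
        mask = xr.DataArray(
            np.array([[False]]), coords={"lat": [0.0], "lon": [0.0]}, dims=("lat", "lon")
        )
        ge = GridExposure(
            mean_days=mean_days.where(mask),
            threshold=25.0,
            n_years=1,
            season="calendar_year",
            mask=mask,
        )
        with pytest.raises(ValueError):
            fraction_range_exposed(ge)


class TestBuffering:
    def test_zero_offset_is_identity(self):
        grid, _ = generate_grid(ClimateParams(n_years=1, seed=2), nlat=2, nlon=2)
        out = apply_buffering(grid, BufferingProfile(0.0, "preserve_relative"))
        assert np.allclose(out.data["tair"], grid.data["tair"])
        assert np.allclose(out.data["rh"], grid.data["rh"])

    def test_preserve_relative_reduces_exposure(self):
        grid, _ = generate_grid(ClimateParams(n_years=2, seed=6), nlat=3, nlon=2)
        ge = grid_exposure(grid, 25.0, season="oct_mar_summer")
        buffered = apply_buffering(grid, BufferingProfile(5.0, "preserve_relative"))
        geb = grid_exposure(buffered, 25.0, season="oct_mar_summer")
        assert np.all(geb.mean_days.values <= ge.mean_days.values)

    def test_preserve_absolute_reduces_exposure_and_reports_clipping(self):
        grid, _ = generate_grid(ClimateParams(n_years=2, seed=6), nlat=3, nlon=2)
        ge = grid_exposure(grid, 25.0, season="oct_mar_summer")
        buffered = apply_buffering(grid, BufferingProfile(5.0, "preserve_absolute"))
        geb = grid_exposure(buffered, 25.0, season="oct_mar_summer")
        assert np.all(geb.mean_days.values <= ge.mean_days.values)
        assert buffered.data.attrs["buffering_clipped_records"] >= 0
        assert np.all(buffered.data["rh"].values <= 100.0)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            BufferingProfile(-1.0, "preserve_relative")


class TestPolygonSampling:
    def test_sampled_mean_matches_uniform_cell(self):
        planted = np.full((2, 2), 7)
        ge = grid_exposure(planted_grid(planted), 25.0, season="calendar_year")
        poly = mapping(box(30.0, -30.0, 32.0, -28.0))
        out = sample_polygon_exposure(ge, [poly], k=5, seed=1)
        assert out[0]["mean_days"] == 7.0
        assert len(out[0]["values"]) == 5

    def test_sampling_is_seeded(self):
        planted = np.array([[5, 0], [2, 12]])
        ge = grid_exposure(planted_grid(planted), 25.0, season="calendar_year")
        poly = mapping(box(30.0, -30.0, 32.0, -28.0))
        a = sample_polygon_exposure(ge, [poly], k=4, seed=3)
        b = sample_polygon_exposure(ge, [poly], k=4, seed=3)
        assert a == b


class TestNetcdfRoundTrip:
    def test_write_then_read(self, tmp_path):
        grid, polygon = generate_grid(ClimateParams(n_years=1, seed=8), nlat=2, nlon=2)
        grid.mask = rasterize_range_mask(grid, polygon)
        path = tmp_path / "grid.nc"
        write_weather_grid(grid, path)
        back = read_weather_grid(path)
        assert np.allclose(back.data["tair"], grid.data["tair"])
        assert np.array_equal(back.mask.values, grid.mask.values)
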