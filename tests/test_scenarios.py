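"""Scenario transforms, attribution partitioning, threshold sensitivity
and measurement-error inversion."""

import numpy as np
import pandas as pd
import pytest

from humidheat import (
    ClimateParams,
    ScenarioSpec,
    WeatherSeries,
    absolute_humidity,
    apply_scenario,
    exceedance_days,
    generate_site_series,
    partition_attribution,
    required_measurement_error,
    rh_from_absolute_humidity,
    saturation_vapour_pressure,
    solve_tair_for_wet_bulb,
    threshold_sensitivity,
    wet_bulb_stull,
)
from humidheat.scenarios import DegenerateAttributionError

from conftest import planted_series


@pytest.fixture(scope="module")
def site_series() -> WeatherSeries:
    return generate_site_series(ClimateParams(n_years=5, seed=3))


class TestApplyScenario:
    def test_zero_delta_is_identity(self, site_series):
        for assumption in ("constant_relative", "constant_absolute"):
            out = apply_scenario(site_series, ScenarioSpec(0.0, assumption))
            assert np.allclose(out.data["tair_c"], site_series.data["tair_c"])
            assert np.allclose(out.data["rh_pct"], site_series.data["rh_pct"])

    def test_constant_absolute_rh_closed_form(self):
        """t = 30, rh = 80, Δ = 4.5: rh' follows the vapour-density ratio."""
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2001-01-01"]),
                "tair_c": [30.0],
                "rh_pct": [80.0],
            }
        )
        series = WeatherSeries(data=df)
        out = apply_scenario(series, ScenarioSpec(4.5, "constant_absolute"))
        # constant vapour density: rh' = rh * (svp(30)/svp(34.5)) * (T'_K/T_K)
        expected = (
            80.0
            * saturation_vapour_pressure(30.0)
            / saturation_vapour_pressure(34.5)
            * (34.5 + 273.15)
            / (30.0 + 273.15)
        )
        assert out.data["rh_pct"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_constant_absolute_preserves_vapour_density(self, site_series):
        out = apply_scenario(site_series, ScenarioSpec(3.0, "constant_absolute"))
        ah0 = absolute_humidity(
            site_series.data["tair_c"].to_numpy(),
            site_series.data["rh_pct"].to_numpy(),
        )
        ah1 = absolute_humidity(
            out.data["tair_c"].to_numpy(), out.data["rh_pct"].to_numpy()
        )
        assert np.allclose(ah0, ah1, rtol=1e-12)

    def test_warming_lowers_rh_under_constant_absolute(self, site_series):
        out = apply_scenario(site_series, ScenarioSpec(2.0, "constant_absolute"))
        assert np.all(out.data["rh_pct"] < site_series.data["rh_pct"])

    def test_cooling_clips_at_saturation(self):
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2001-01-01"]),
                "tair_c": [25.0],
                "rh_pct": [99.0],
            }
        )
        out = apply_scenario(
            WeatherSeries(data=df), ScenarioSpec(-5.0, "constant_absolute")
        )
        assert out.data["rh_pct"].iloc[0] == 100.0

    def test_constant_relative_raises_wet_bulb_more(self, site_series):
        const_rh = apply_scenario(site_series, ScenarioSpec(3.0, "constant_relative"))
        const_ah = apply_scenario(site_series, ScenarioSpec(3.0, "constant_absolute"))
        tw0 = wet_bulb_stull(
            site_series.data["tair_c"].to_numpy(),
            site_series.data["rh_pct"].to_numpy(),
        )
        tw_rh = wet_bulb_stull(
            const_rh.data["tair_c"].to_numpy(), const_rh.data["rh_pct"].to_numpy()
        )
        tw_ah = wet_bulb_stull(
            const_ah.data["tair_c"].to_numpy(), const_ah.data["rh_pct"].to_numpy()
        )
        assert np.all(tw_rh > tw_ah) and np.all(tw_ah > tw0)

    def test_provenance_records_spec(self, site_series):
        out = apply_scenario(
            site_series, ScenarioSpec(4.5, "constant_relative", label="SSP5-8.5")
        )
        assert "SSP5-8.5" in out.provenance and "constant_relative" in out.provenance

    def test_invalid_assumption_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(2.0, "constant_specific")


class TestAttribution:
    def test_planted_two_and_ten_extra_days(self):
        """Constructed partition: ΔE_ah = 2, ΔE_rh = 10 d yr⁻¹ → 0.2/0.8.

        Day placement is derived from the psychrometric primitives alone
        (not from the scenario code under test): for each candidate
        wet-bulb value we compute where it lands after a +Δ shift under
        each humidity assumption, then plant 2 days that cross the
        threshold under both assumptions and 8 that cross only when
        relative humidity is held constant.
        """
        from conftest import FIXTURE_RH, tair_for_tw

        delta, threshold = 2.0, 25.0

        def shifted(v):
            t = tair_for_tw(v)
            tw_rh = wet_bulb_stull(t + delta, FIXTURE_RH)
            ah = absolute_humidity(t, FIXTURE_RH)
            tw_ah = wet_bulb_stull(
                t + delta, rh_from_absolute_humidity(t + delta, ah)
            )
            return tw_ah, tw_rh

        both, rh_only = [], []
        for v in np.arange(22.0, 24.99, 0.01):
            tw_ah, tw_rh = shifted(v)
            if tw_ah >= threshold and tw_rh >= threshold:
                both.append(v)
            elif tw_rh >= threshold and tw_ah < threshold:
                rh_only.append(v)
        assert len(both) >= 2 and len(rh_only) >= 8
        values = both[:2] + rh_only[:8]
        series = planted_series(15.0, {0: values}, n_seasons=1)
        att = partition_attribution(series, delta, threshold)
        assert att.exposure_baseline == 0.0
        assert att.exposure_const_ah == 2.0
        assert att.exposure_const_rh == 10.0
        assert att.frac_tair == pytest.approx(0.2)
        assert att.frac_humidity == pytest.approx(0.8)

    def test_fractions_from_exposure_arithmetic(self, site_series):
        att = partition_attribution(site_series, 4.5, 26.0)
        e0, eah, erh = (
            att.exposure_baseline,
            att.exposure_const_ah,
            att.exposure_const_rh,
        )
        assert att.frac_tair == pytest.approx((eah - e0) / (erh - e0), abs=1e-15)
        assert att.frac_tair + att.frac_humidity == 1.0
        assert e0 <= eah <= erh

    def test_attribution_threshold_scale_invariance(self, site_series):
        # fractions do not depend on how many seasons the mean divides by
        att = partition_attribution(site_series, 4.5, 26.0)
        assert 0.0 <= att.frac_tair <= 1.0

    def test_zero_denominator_raises(self):
        # bone-dry series: no scenario produces exceedance at a high threshold
        series = planted_series(15.0, {}, n_seasons=1)
        with pytest.raises(DegenerateAttributionError):
            partition_attribution(series, 1.0, 40.0)


class TestSensitivity:
    def test_zero_offset_reproduces_unperturbed_summary(self, tiered_series):
        res = threshold_sensitivity(tiered_series, 25.0, offsets=(0.0,))
        direct = exceedance_days(tiered_series, 25.0)
        assert res.exposures[0] == direct.mean_days_per_year

    def test_planted_counts_across_offsets(self, tiered_series):
        res = threshold_sensitivity(
            tiered_series, 25.0, offsets=(-2.0, -1.0, 0.0, 1.0, 2.0)
        )
        assert list(res.exposures) == [12, 8, 8, 5, 5]

    def test_exposures_weakly_decreasing(self, site_series):
        res = threshold_sensitivity(site_series, 26.0)
        assert list(res.exposures) == sorted(res.exposures, reverse=True)


class TestMeasurementError:
    def test_zero_delta_needs_zero_error(self):
        assert required_measurement_error(0.0) == (0.0, 0.0)

    def test_chamber_base_state_inversions(self):
        """A 2 °C wet-bulb error needs ≈ 7 °C in T_air or ≈ 20% in AH."""
        dt_air, dah_pct = required_measurement_error(2.0, ah=25.0, threshold=31.7)
        assert dt_air == pytest.approx(7.0, abs=1.0)
        assert dah_pct == pytest.approx(20.0, abs=1.0)

    def test_base_state_reconstruction(self):
        t0 = solve_tair_for_wet_bulb(25.0, 31.7)
        tw = wet_bulb_stull(t0, rh_from_absolute_humidity(t0, 25.0))
        assert tw == pytest.approx(31.7, abs=2e-3)

    def test_increasing_in_delta_tw(self):
        prev = (0.0, 0.0)
        for d in (0.5, 1.0, 1.5, 2.0):
            cur = required_measurement_error(d)
            assert cur[0] > prev[0] and cur[1] > prev[1]
            prev = cur

    def test_errors_solve_the_stated_equations(self):
        dt_air, dah_pct = required_measurement_error(1.0, ah=25.0, threshold=31.7)
        t0 = solve_tair_for_wet_bulb(25.0, 31.7)
        tw_t = wet_bulb_stull(
            t0 + dt_air, rh_from_absolute_humidity(t0 + dt_air, 25.0)
        )
        tw_a = wet_bulb_stull(
            t0, rh_from_absolute_humidity(t0, 25.0 * (1 + dah_pct / 100))
        )
        target = wet_bulb_stull(t0, rh_from_absolute_humidity(t0, 25.0)) + 1.0
        assert tw_t == pytest.approx(target, abs=5e-3)
        assert tw_a == pytest.approx(target, abs=5e-3)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            required_measurement_error(-1.0)
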