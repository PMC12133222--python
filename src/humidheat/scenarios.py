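"""Future-climate scenarios, warming/humidification attribution and
threshold sensitivity.

A scenario applies a uniform air-temperature increment ΔT to a weather
series under one of two humidity assumptions:

``constant_relative``
    Relative humidity unchanged — absolute humidity rises with
    temperature (the assumption considered most likely for many humid
    regions).
``constant_absolute``
    Vapour density unchanged — relative humidity falls as temperature
    rises.

Comparing exceedance under the two assumptions against the baseline
partitions the projected increase in exposure between warming per se
(the constant-absolute-humidity response) and humidification (the
remainder). A separate routine inverts the wet-bulb formula to express a
wet-bulb error as the equivalent measurement error in air temperature or
in absolute humidity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exposure import (
    DEFAULT_DAYTIME_WINDOW,
    ExposureSummary,
    WeatherSeries,
    exceedance_days,
)
from .psychro import (
    absolute_humidity,
    rh_from_absolute_humidity,
    saturation_temperature,
    wet_bulb_stull,
)

__all__ = [
    "ScenarioSpec",
    "AttributionResult",
    "SensitivityResult",
    "apply_scenario",
    "partition_attribution",
    "threshold_sensitivity",
    "required_measurement_error",
    "solve_tair_for_wet_bulb",
    "DegenerateAttributionError",
]

logger = logging.getLogger(__name__)

HUMIDITY_ASSUMPTIONS = ("constant_relative", "constant_absolute")


class DegenerateAttributionError(ArithmeticError):
    """The scenario produced no increase in exposure to partition."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A future-climate transformation of a weather series.

    ``delta_t`` is the uniform air-temperature increment (°C), e.g. the
    projected end-century rise for an emissions pathway;
    ``humidity_assumption`` is ``constant_relative`` or
    ``constant_absolute``; ``label`` is free text (e.g. "SSP2-4.5").
    """

    delta_t: float
    humidity_assumption: str
    label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.delta_t):
            raise ValueError("delta_t must be finite")
        if self.humidity_assumption not in HUMIDITY_ASSUMPTIONS:
            raise ValueError(
                f"humidity_assumption must be one of {HUMIDITY_ASSUMPTIONS}"
            )


@dataclass(frozen=True)
class AttributionResult:
    """Partition of increased exposure between warming and humidification.

    ``frac_tair`` is (E_const_ah − E_baseline) / (E_const_rh − E_baseline);
    ``frac_humidity`` its complement. The two sum to 1 exactly whenever
    the exposures are ordered baseline ≤ const_ah ≤ const_rh
    (``ordering_ok``); otherwise the fractions are NaN.
    """

    exposure_baseline: float
    exposure_const_rh: float
    exposure_const_ah: float
    frac_tair: float
    frac_humidity: float
    delta_t: float
    threshold: float
    ordering_ok: bool = True

    def as_dict(self) -> dict:
        return {
            "exposure_baseline_days": self.exposure_baseline,
            "exposure_const_rh_days": self.exposure_const_rh,
            "exposure_const_ah_days": self.exposure_const_ah,
            "frac_tair": self.frac_tair,
            "frac_humidity": self.frac_humidity,
            "delta_t_c": self.delta_t,
            "threshold_c": self.threshold,
            "ordering_ok": self.ordering_ok,
        }


@dataclass(frozen=True)
class SensitivityResult:
    """Exposure as a function of threshold offset.

    ``exposures[i]`` is the mean exceedance days yr⁻¹ at
    ``threshold + offsets[i]``; summaries are retained per offset.
    """

    threshold: float
    offsets: tuple[float, ...]
    exposures: tuple[float, ...]
    summaries: tuple[ExposureSummary, ...] = field(default=(), repr=False)

    def as_dict(self) -> dict:
        return {
            "threshold_c": self.threshold,
            "offsets_c": list(self.offsets),
            "mean_days_per_year": list(self.exposures),
        }


def apply_scenario(series: WeatherSeries, spec: ScenarioSpec) -> WeatherSeries:
    """Transform a weather series to a future-climate scenario.

    ``constant_relative``: t → t + Δ, rh unchanged. ``constant_absolute``:
    each record's vapour density is held fixed and rh recomputed at
    t + Δ; for Δ > 0 rh strictly falls, for Δ < 0 supersaturated values
    are clipped to 100% and the count logged.
    """
    df = series.data.copy()
    t = df["tair_c"].to_numpy(float)
    rh = df["rh_pct"].to_numpy(float)
    t_new = t + spec.delta_t
    if spec.humidity_assumption == "constant_relative":
        rh_new = rh
    else:
        ah = absolute_humidity(t, rh)
        rh_new = rh_from_absolute_humidity(t_new, ah, clip=True)
        n_clip = int(np.sum(rh_new >= 100.0 - 1e-12))
        if n_clip and spec.delta_t < 0:
            logger.info("scenario clipped %d supersaturated records", n_clip)
    df["tair_c"] = t_new
    df["rh_pct"] = rh_new
    out = WeatherSeries(
        data=df,
        cadence=series.cadence,
        site=series.site,
        lat=series.lat,
        lon=series.lon,
        provenance=series.provenance,
    )
    label = spec.label or "scenario"
    return out.with_provenance(
        f"{label}: delta_t={spec.delta_t:+g} C, {spec.humidity_assumption}"
    )


def partition_attribution(
    series: WeatherSeries,
    delta_t: float,
    threshold: float,
    season: str = "oct_mar_summer",
    window: tuple[int, int] = DEFAULT_DAYTIME_WINDOW,
) -> AttributionResult:
    """Partition the scenario-driven increase in exceedance days.

    Computes baseline exposure E0, exposure under constant absolute
    humidity E_ah and under constant relative humidity E_rh for the same
    ΔT, then frac_tair = (E_ah − E0)/(E_rh − E0). Raises
    :class:`DegenerateAttributionError` when E_rh = E0 (nothing to
    partition).
    """

    def expo(s: WeatherSeries) -> float:
        return exceedance_days(s, threshold, season=season, window=window).mean_days_per_year

    e0 = expo(series)
    e_ah = expo(
        apply_scenario(series, ScenarioSpec(delta_t, "constant_absolute"))
    )
    e_rh = expo(
        apply_scenario(series, ScenarioSpec(delta_t, "constant_relative"))
    )
    if e_rh == e0:
        raise DegenerateAttributionError(
            f"constant-RH scenario adds no exceedance days (E0 = E_rh = {e0}); "
            "attribution undefined"
        )
    ordering_ok = e0 <= e_ah <= e_rh if delta_t > 0 else True
    if ordering_ok:
        frac_tair = (e_ah - e0) / (e_rh - e0)
        frac_humidity = 1.0 - frac_tair
    else:
        logger.warning(
            "exposure ordering violated (E0=%s, E_ah=%s, E_rh=%s); "
            "fractions undefined",
            e0, e_ah, e_rh,
        )
        frac_tair = frac_humidity = float("nan")
    return AttributionResult(
        exposure_baseline=e0,
        exposure_const_rh=e_rh,
        exposure_const_ah=e_ah,
        frac_tair=frac_tair,
        frac_humidity=frac_humidity,
        delta_t=delta_t,
        threshold=threshold,
        ordering_ok=ordering_ok,
    )


def threshold_sensitivity(
    series: WeatherSeries,
    threshold: float,
    offsets: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    season: str = "oct_mar_summer",
    window: tuple[int, int] = DEFAULT_DAYTIME_WINDOW,
) -> SensitivityResult:
    """Exposure recomputed at threshold + each offset.

    Models the effect of the species threshold being over- or
    underestimated; exposures are non-increasing in the offset.
    """
    summaries = tuple(
        exceedance_days(series, threshold + off, season=season, window=window)
        for off in offsets
    )
    return SensitivityResult(
        threshold=float(threshold),
        offsets=tuple(float(o) for o in offsets),
        exposures=tuple(s.mean_days_per_year for s in summaries),
        summaries=summaries,
    )


def solve_tair_for_wet_bulb(ah: float, target_tw: float) -> float:
    """Air temperature (°C) at which air holding ``ah`` g m⁻³ has the
    given Stull wet-bulb temperature.

    Bracketed between the saturation temperature of ``ah`` (where
    t_wet = t_air) and 60 °C; tolerance 0.001 °C.
    """
    t_sat = saturation_temperature(ah)

    # clip=True guards the lower bracket edge, which sits within the
    # saturation root-finder's tolerance of rh = 100%.
    def f(t):
        return wet_bulb_stull(
            t, rh_from_absolute_humidity(t, ah, clip=True), warn_envelope=False
        ) - target_tw

    lo, hi = t_sat + 1e-6, 60.0
    if f(lo) * f(hi) > 0:
        raise ArithmeticError(
            f"no air temperature in ({lo:.2f}, {hi}) °C gives wet-bulb "
            f"{target_tw} °C at ah = {ah} g m-3"
        )
    return brentq(f, lo, hi, xtol=1e-3)


def required_measurement_error(
    delta_tw: float,
    ah: float = 25.0,
    threshold: float = 31.7,
    t_air: float | None = None,
) -> tuple[float, float]:
    """Measurement errors equivalent to a wet-bulb error of ``delta_tw``.

    The base state defaults to the high-humidity heat-tolerance trial:
    absolute humidity ``ah`` (g m⁻³) with air temperature solved so the
    Stull wet-bulb equals ``threshold`` (pass ``t_air`` to override).
    Returns ``(dt_air, dah_pct)``:

    * ``dt_air`` — the increase in air temperature (°C), absolute
      humidity held fixed, that raises the wet-bulb by ``delta_tw``;
    * ``dah_pct`` — the relative increase in absolute humidity (%), air
      temperature held fixed, doing the same.

    Both found by bracketed root-finding to 0.001 tolerance.
    """
    if delta_tw < 0:
        raise ValueError("delta_tw must be non-negative")
    if delta_tw == 0:
        return 0.0, 0.0
    t0 = solve_tair_for_wet_bulb(ah, threshold) if t_air is None else float(t_air)
    tw0 = wet_bulb_stull(
        t0, rh_from_absolute_humidity(t0, ah), warn_envelope=False
    )
    target = tw0 + delta_tw

    def f_t(dt):
        t = t0 + dt
        return wet_bulb_stull(
            t, rh_from_absolute_humidity(t, ah), warn_envelope=False
        ) - target

    hi = 60.0 - t0
    if f_t(hi) < 0:
        raise ArithmeticError(
            f"air-temperature bracket (0, {hi:.1f}) °C cannot raise the "
            f"wet-bulb by {delta_tw} °C"
        )
    dt_air = brentq(f_t, 0.0, hi, xtol=1e-3)

    # Upper bracket for the humidity perturbation: saturation at t0.
    ah_sat = absolute_humidity(t0, 100.0)
    p_max = 100.0 * (ah_sat / ah - 1.0) - 1e-9

    def f_p(p):
        rh = rh_from_absolute_humidity(t0, ah * (1.0 + p / 100.0))
        return wet_bulb_stull(t0, rh, warn_envelope=False) - target

    if p_max <= 0 or f_p(p_max) < 0:
        raise ArithmeticError(
            f"humidity perturbation reaches saturation (at +{p_max:.1f}%) "
            f"before raising the wet-bulb by {delta_tw} °C"
        )
    dah_pct = brentq(f_p, 0.0, p_max, xtol=1e-3)
    return dt_air, dah_pct
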