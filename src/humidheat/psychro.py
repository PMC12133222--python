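"""Psychrometric state conversions and wet-bulb temperature.

All humid-air quantities used in the package funnel through this module:
saturation vapour pressure (Magnus form, WMO coefficients), vapour
pressure / relative humidity / absolute humidity (vapour density)
interconversions, dewpoint, and two wet-bulb temperature estimators —
the Stull (2011) closed-form approximation used throughout the analysis
pipeline, and an iterative solution of the psychrometer equation kept as
an independent cross-check.

Functions accept scalars or numpy arrays and are pure (no I/O).
Temperatures are in °C, pressures in hPa, relative humidity in percent,
absolute humidity in g m⁻³.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "SupersaturationError",
    "PsychroState",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "absolute_humidity",
    "rh_from_absolute_humidity",
    "dewpoint",
    "dewpoint_from_ah",
    "saturation_temperature",
    "wet_bulb_stull",
    "wet_bulb_iterative",
    "psychro_state",
    "STANDARD_PRESSURE_HPA",
]

# Magnus saturation-vapour-pressure coefficients (WMO form, over water).
_MAGNUS_A = 6.112   # hPa
_MAGNUS_B = 17.62
_MAGNUS_C = 243.12  # °C

# Vapour density constant: ah [g m-3] = _GAS_C * e [hPa] / T [K].
# This is 1e5 / R_v with R_v = 461.5 J kg-1 K-1 folded into g/hPa units.
_GAS_C = 216.7

STANDARD_PRESSURE_HPA = 1013.25

# Validity bounds for the Magnus fit (over liquid water).
_T_MIN, _T_MAX = -40.0, 60.0

# Published applicability envelope of the Stull wet-bulb fit at sea level.
_STULL_T_MIN, _STULL_T_MAX = -20.0, 50.0
_STULL_RH_MIN = 5.0

# Psychrometer coefficient (ventilated, A*P in hPa K-1 with P in hPa).
_PSYCHROMETER_A = 6.62e-4


class DomainError(ValueError):
    """An input lies outside the validity range of a formula."""


class SupersaturationError(ValueError):
    """A humidity conversion implies relative humidity above 100%."""


class StullEnvelopeWarning(UserWarning):
    """Inputs fall outside the published fit envelope of the Stull formula."""


@dataclass(frozen=True)
class PsychroState:
    """One atmospheric state with mutually consistent humidity measures.

    Attributes
    ----------
    t_air : float
        Dry-bulb air temperature, °C.
    rh : float
        Relative humidity, % of saturation, in (0, 100].
    e : float
        Water vapour partial pressure, hPa.
    ah : float
        Absolute humidity (vapour density), g m⁻³.
    t_dew : float
        Dewpoint temperature, °C.
    t_wet : float
        Wet-bulb temperature (Stull approximation), °C.
    pressure : float
        Barometric pressure, hPa. Default sea level.
    """

    t_air: float
    rh: float
    e: float
    ah: float
    t_dew: float
    t_wet: float
    pressure: float = STANDARD_PRESSURE_HPA

    def as_dict(self) -> dict:
        return {
            "t_air_c": self.t_air,
            "rh_pct": self.rh,
            "vapour_pressure_hpa": self.e,
            "absolute_humidity_gm3": self.ah,
            "dewpoint_c": self.t_dew,
            "wet_bulb_c": self.t_wet,
            "pressure_hpa": self.pressure,
        }


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite")


def saturation_vapour_pressure(t):
    """Saturation vapour pressure over liquid water, hPa.

    Magnus form e_s(t) = 6.112 exp(17.62 t / (243.12 + t)), valid for
    −40 ≤ t ≤ 60 °C. Strictly increasing in t.
    """
    t = np.asarray(t, dtype=float)
    _check_finite("temperature", t)
    if np.any(t < _T_MIN) or np.any(t > _T_MAX):
        raise DomainError(
            f"temperature outside [{_T_MIN}, {_T_MAX}] °C for the "
            "saturation vapour pressure formula"
        )
    out = _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))
    return float(out) if out.ndim == 0 else out


def vapour_pressure(t, rh):
    """Actual vapour pressure e = rh/100 · e_s(t), hPa."""
    rh = np.asarray(rh, dtype=float)
    _check_finite("relative humidity", rh)
    if np.any(rh <= 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be in (0, 100] %")
    out = rh / 100.0 * saturation_vapour_pressure(t)
    return float(out) if np.ndim(out) == 0 else out


def absolute_humidity(t, rh):
    """Absolute humidity (vapour density), g m⁻³, from t (°C) and rh (%).

    ah = 216.7 · e / T_K with e the actual vapour pressure in hPa.
    """
    e = vapour_pressure(t, rh)
    t = np.asarray(t, dtype=float)
    out = _GAS_C * e / (t + 273.15)
    return float(out) if np.ndim(out) == 0 else out


def rh_from_absolute_humidity(t, ah, *, clip: bool = False):
    """Relative humidity (%) of air at t °C holding ah g m⁻³ of vapour.

    Exact algebraic inverse of :func:`absolute_humidity`. If the implied
    rh exceeds 100% (supersaturation) a :class:`SupersaturationError` is
    raised unless ``clip=True``, in which case values are clipped to 100.
    """
    ah = np.asarray(ah, dtype=float)
    _check_finite("absolute humidity", ah)
    if np.any(ah <= 0):
        raise ValueError("absolute humidity must be positive")
    t_arr = np.asarray(t, dtype=float)
    es = saturation_vapour_pressure(t)
    rh = 100.0 * ah * (t_arr + 273.15) / (_GAS_C * es)
    if np.any(rh > 100.0 + 1e-9):
        if clip:
            rh = np.minimum(rh, 100.0)
        else:
            raise SupersaturationError(
                "absolute humidity implies relative humidity above 100% "
                f"(max implied rh = {float(np.max(rh)):.2f}%)"
            )
    rh = np.minimum(rh, 100.0)
    return float(rh) if rh.ndim == 0 else rh


def dewpoint(t, rh):
    """Isobaric dewpoint, °C: the temperature at which the parcel's
    vapour pressure equals saturation.

    Closed-form inversion of the Magnus formula; dewpoint(t, 100) = t.
    """
    e = vapour_pressure(t, rh)
    x = np.log(np.asarray(e, dtype=float) / _MAGNUS_A)
    out = _MAGNUS_C * x / (_MAGNUS_B - x)
    return float(out) if np.ndim(out) == 0 else out


def dewpoint_from_ah(ah, t_air):
    """Dewpoint, °C, of air at ``t_air`` °C holding ``ah`` g m⁻³ of vapour.

    The vapour density is converted to vapour pressure at the parcel's
    actual temperature (e = ah·T_K/216.7) and the Magnus formula inverted;
    this is the standard isobaric dewpoint of the stated state. A reference
    air temperature is required because a vapour density alone does not fix
    the vapour pressure.
    """
    return dewpoint(t_air, rh_from_absolute_humidity(t_air, ah))


def saturation_temperature(ah) -> float:
    """Temperature (°C) at which saturated vapour density equals ``ah``.

    Found by bracketed root-finding on (−40, 60) °C to 0.001 °C. This is
    the temperature at which air holding ``ah`` g m⁻³ reaches rh = 100%
    (cooling at constant vapour density); it sits slightly below the
    isobaric dewpoint of warmer air with the same vapour density.
    """
    ah = float(ah)
    if not np.isfinite(ah) or ah <= 0:
        raise ValueError("absolute humidity must be positive and finite")

    def f(td):
        return _GAS_C * saturation_vapour_pressure(td) / (td + 273.15) - ah

    lo, hi = _T_MIN + 1e-6, _T_MAX - 1e-6
    if f(lo) * f(hi) > 0:
        raise DomainError(
            f"no saturation temperature in ({_T_MIN}, {_T_MAX}) °C for "
            f"ah = {ah} g m⁻³"
        )
    return brentq(f, lo, hi, xtol=1e-3)


def wet_bulb_stull(t, rh, *, warn_envelope: bool = True):
    """Wet-bulb temperature, °C, by the Stull (2011) closed-form fit.

    T_W = t·atan(0.151977 (rh + 8.313659)^½) + atan(t + rh)
          − atan(rh − 1.676331) + 0.00391838 rh^{3/2} atan(0.023101 rh)
          − 4.686035

    The fit was made for sea-level pressure over roughly rh ≥ 5% and
    −20 ≤ t ≤ 50 °C; outside that envelope the value is still computed
    but a :class:`StullEnvelopeWarning` is emitted.
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    _check_finite("temperature", t)
    _check_finite("relative humidity", rh)
    if warn_envelope and (
        np.any(t < _STULL_T_MIN)
        or np.any(t > _STULL_T_MAX)
        or np.any(rh < _STULL_RH_MIN)
        or np.any(rh > 100.0)
    ):
        warnings.warn(
            "inputs outside the Stull fit envelope "
            f"(t in [{_STULL_T_MIN}, {_STULL_T_MAX}] °C, rh >= {_STULL_RH_MIN}%); "
            "value computed anyway",
            StullEnvelopeWarning,
            stacklevel=2,
        )
    out = (
        t * np.arctan(0.151977 * np.sqrt(rh + 8.313659))
        + np.arctan(t + rh)
        - np.arctan(rh - 1.676331)
        + 0.00391838 * rh ** 1.5 * np.arctan(0.023101 * rh)
        - 4.686035
    )
    return float(out) if out.ndim == 0 else out


def wet_bulb_iterative(t, rh, pressure: float = STANDARD_PRESSURE_HPA) -> float:
    """Wet-bulb temperature, °C, as the root of the psychrometer balance.

    Solves e(t, rh) = e_s(t_w) − A·P·(t − t_w) for t_w, bracketed in
    [t_dew − 0.5, t], to 0.001 °C. Scalar only; used as the independent
    oracle for :func:`wet_bulb_stull`.
    """
    t = float(t)
    e = vapour_pressure(t, rh)
    td = dewpoint(t, rh)

    def balance(tw):
        return saturation_vapour_pressure(tw) - _PSYCHROMETER_A * pressure * (t - tw) - e

    lo, hi = td - 0.5, t + 1e-9
    if balance(lo) * balance(hi) > 0:
        raise ArithmeticError(
            "psychrometer balance has no root in bracket "
            f"[{lo:.3f}, {hi:.3f}] for t={t}, rh={rh}, p={pressure}"
        )
    return brentq(balance, lo, hi, xtol=1e-3)


def psychro_state(
    t: float,
    rh: float | None = None,
    ah: float | None = None,
    pressure: float = STANDARD_PRESSURE_HPA,
) -> PsychroState:
    """Build a fully populated :class:`PsychroState` from one humidity measure.

    Exactly one of ``rh`` (percent) or ``ah`` (g m⁻³) must be given; the
    remaining fields are filled so that the state's invariants hold.
    """
    if (rh is None) == (ah is None):
        raise ValueError("supply exactly one of rh (percent) or ah (g m-3)")
    t = float(t)
    if rh is None:
        rh = rh_from_absolute_humidity(t, float(ah))
    rh = float(rh)
    e = vapour_pressure(t, rh)
    return PsychroState(
        t_air=t,
        rh=rh,
        e=e,
        ah=absolute_humidity(t, rh),
        t_dew=dewpoint(t, rh),
        t_wet=wet_bulb_stull(t, rh),
        pressure=float(pressure),
    )
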