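"""Species maximum wet-bulb temperature (T_W-max) from thermal endpoints.

A heat-tolerance trial ramps chamber air temperature at a controlled
absolute humidity until the bird reaches a thermal endpoint. A record
qualifies as evidence of the species' maximum tolerable wet-bulb
temperature when two criteria hold jointly:

1. evaporative cooling has failed — the bird can no longer hold body
   temperature below environmental (chamber air) temperature; and
2. hyperthermia is severe — locomotor function (coordination, balance,
   righting) is compromised.

For qualifying records the wet-bulb temperature at the endpoint is
computed from the chamber state (air temperature, treatment absolute
humidity) and the species threshold is summarised as mean ± SD with range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .psychro import SupersaturationError, rh_from_absolute_humidity, wet_bulb_stull

__all__ = [
    "EndpointRecord",
    "TwMaxEstimate",
    "qualifies_as_twmax_endpoint",
    "endpoint_wet_bulb",
    "estimate_twmax",
    "read_endpoint_csv",
    "NoQualifyingRecordsError",
]

ENDPOINT_REASONS = ("tb_runaway", "coordination_loss", "ewl_decline", "rmr_decline")


class NoQualifyingRecordsError(ValueError):
    """No record met both threshold criteria."""


@dataclass(frozen=True)
class EndpointRecord:
    """One bird's thermal-endpoint observation.

    Parameters
    ----------
    bird_id : str
        Opaque identifier.
    sex : str
        One of ``{"M", "F", "unknown"}``.
    mass : float
        Body mass at capture, g.
    treatment_ah : float
        Chamber absolute humidity, g m⁻³ (nominal treatments 6 / 13 / 25).
    t_air_end : float
        Chamber air temperature at the endpoint, °C.
    t_b_end : float
        Body temperature at the endpoint, °C.
    locomotor_impaired : bool
        Loss of coordination, balance or righting observed.
    endpoint_reason : str
        One of ``{"tb_runaway", "coordination_loss", "ewl_decline",
        "rmr_decline"}``.
    ewl, rmr : float, optional
        Evaporative water loss (g h⁻¹) and resting metabolic rate (W)
        at the endpoint; carried as payload only.
    """

    bird_id: str
    sex: str
    mass: float
    treatment_ah: float
    t_air_end: float
    t_b_end: float
    locomotor_impaired: bool
    endpoint_reason: str
    ewl: float | None = None
    rmr: float | None = None

    def __post_init__(self):
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"{self.bird_id}: sex must be M, F or unknown")
        if not (self.mass > 0):
            raise ValueError(f"{self.bird_id}: mass must be positive")
        if not (self.treatment_ah > 0):
            raise ValueError(f"{self.bird_id}: treatment_ah must be positive")
        if not (25.0 <= self.t_air_end <= 56.0):
            raise ValueError(
                f"{self.bird_id}: t_air_end {self.t_air_end} outside [25, 56] °C"
            )
        if not (38.0 <= self.t_b_end <= 48.0):
            raise ValueError(
                f"{self.bird_id}: t_b_end {self.t_b_end} outside [38, 48] °C"
            )
        if self.endpoint_reason not in ENDPOINT_REASONS:
            raise ValueError(
                f"{self.bird_id}: endpoint_reason must be one of {ENDPOINT_REASONS}"
            )


@dataclass(frozen=True)
class TwMaxEstimate:
    """Aggregated species maximum wet-bulb temperature.

    ``sd`` uses the sample (n−1) convention; for n = 1 it is reported as
    0.0 with ``sd_defined=False``. ``per_bird`` lists (bird_id, endpoint
    wet-bulb °C) for every qualifying record.
    """

    mean: float
    sd: float
    min: float
    max: float
    n: int
    per_bird: list[tuple[str, float]] = field(default_factory=list)
    sd_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "twmax_mean_c": self.mean,
            "twmax_sd_c": self.sd,
            "twmax_min_c": self.min,
            "twmax_max_c": self.max,
            "n_birds": self.n,
            "sd_defined": self.sd_defined,
            "per_bird": [{"bird_id": b, "tw_c": tw} for b, tw in self.per_bird],
        }


def qualifies_as_twmax_endpoint(rec: EndpointRecord) -> tuple[bool, list[str]]:
    """Apply the two joint threshold criteria to one record.

    Returns ``(True, [])`` iff body temperature at the endpoint is at or
    above chamber air temperature (evaporative cooling failure; a tie
    counts as failure to stay below) AND locomotor impairment was
    observed. Otherwise returns ``(False, reasons)`` naming each failed
    criterion.
    """
    reasons = []
    if rec.t_b_end < rec.t_air_end:
        reasons.append("t_b below environment")
    if not rec.locomotor_impaired:
        reasons.append("no locomotor impairment")
    return (not reasons, reasons)


def endpoint_wet_bulb(rec: EndpointRecord) -> float:
    """Wet-bulb temperature (°C) of the chamber state at the endpoint.

    Chamber environmental temperature is taken to equal chamber air
    temperature (no radiant correction); the treatment absolute humidity
    is converted to relative humidity at that temperature and the Stull
    formula applied.
    """
    try:
        rh = rh_from_absolute_humidity(rec.t_air_end, rec.treatment_ah)
    except SupersaturationError as err:
        raise ValueError(
            f"bird {rec.bird_id}: treatment humidity {rec.treatment_ah} g m-3 "
            f"supersaturates the chamber at t_air = {rec.t_air_end} °C"
        ) from err
    return wet_bulb_stull(rec.t_air_end, rh)


def estimate_twmax(records: list[EndpointRecord]) -> TwMaxEstimate:
    """Species T_W-max from a set of endpoint records.

    Records failing either threshold criterion are excluded; the wet-bulb
    temperatures of the remainder are summarised as mean, sample SD
    (n−1 denominator), min, max and count. Order-independent.
    """
    per_bird = [
        (rec.bird_id, endpoint_wet_bulb(rec))
        for rec in records
        if qualifies_as_twmax_endpoint(rec)[0]
    ]
    if not per_bird:
        raise NoQualifyingRecordsError(
            "no record met both criteria (t_b >= t_air and locomotor impairment)"
        )
    tw = np.array([v for _, v in per_bird])
    n = len(tw)
    return TwMaxEstimate(
        mean=float(tw.mean()),
        sd=float(tw.std(ddof=1)) if n > 1 else 0.0,
        min=float(tw.min()),
        max=float(tw.max()),
        n=n,
        per_bird=per_bird,
        sd_defined=n > 1,
    )


def read_endpoint_csv(path: str | Path) -> list[EndpointRecord]:
    """Read an endpoint table.

    Expected columns: ``bird_id, sex, mass_g, treatment_ah_gm3,
    tair_end_c, tb_end_c, locomotor_impaired`` (0/1), ``endpoint_reason``;
    optional ``ewl_gh, rmr_w``.
    """
    df = pd.read_csv(path)
    required = {
        "bird_id", "sex", "mass_g", "treatment_ah_gm3",
        "tair_end_c", "tb_end_c", "locomotor_impaired", "endpoint_reason",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"endpoint table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            EndpointRecord(
                bird_id=str(row.bird_id),
                sex=str(row.sex),
                mass=float(row.mass_g),
                treatment_ah=float(row.treatment_ah_gm3),
                t_air_end=float(row.tair_end_c),
                t_b_end=float(row.tb_end_c),
                locomotor_impaired=bool(int(row.locomotor_impaired)),
                endpoint_reason=str(row.endpoint_reason),
                ewl=float(row.ewl_gh) if "ewl_gh" in df.columns else None,
                rmr=float(row.rmr_w) if "rmr_w" in df.columns else None,
            )
        )
    return records


def write_endpoint_csv(records: list[EndpointRecord], path: str | Path) -> None:
    """Write endpoint records in the CSV layout read_endpoint_csv expects."""
    rows = [
        {
            "bird_id": r.bird_id,
            "sex": r.sex,
            "mass_g": r.mass,
            "treatment_ah_gm3": r.treatment_ah,
            "tair_end_c": r.t_air_end,
            "tb_end_c": r.t_b_end,
            "locomotor_impaired": int(r.locomotor_impaired),
            "endpoint_reason": r.endpoint_reason,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
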