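"""Shared run configuration and reproducibility headers for outputs."""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass

from .exposure import DEFAULT_DAYTIME_WINDOW, SEASONS

__all__ = ["RunConfig", "result_envelope", "parse_window", "setup_logging"]

DEFAULT_THRESHOLD_C = 31.7  # species maximum wet-bulb temperature, °C


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings shared by the command-line subcommands.

    The exceedance comparison is fixed at ≥ (a day at exactly the
    threshold counts); ``threshold`` defaults to the species maximum
    wet-bulb temperature of 31.7 °C.
    """

    threshold: float = DEFAULT_THRESHOLD_C
    season: str = "oct_mar_summer"
    daytime_window: tuple[int, int] = DEFAULT_DAYTIME_WINDOW
    comparison: str = ">="
    pressure: float = 1013.25
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not float("-inf") < self.threshold < float("inf"):
            raise ValueError("threshold must be finite")
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")
        lo, hi = self.daytime_window
        if not (0 <= lo < hi <= 24):
            raise ValueError("daytime window must satisfy 0 <= start < end <= 24")


def package_version() -> str:
    from . import __version__

    return __version__


def result_envelope(config: RunConfig, result: dict) -> dict:
    """Wrap a result dict with the resolved config and package version."""
    return {
        "package": "humidheat",
        "version": package_version(),
        "config": asdict(config),
        "result": result,
    }


def parse_window(text: str) -> tuple[int, int]:
    """Parse a daytime window like ``06:00-18:00`` or ``6-18``."""
    try:
        lo, hi = text.split("-")
        lo = int(lo.split(":")[0])
        hi = int(hi.split(":")[0])
    except ValueError as err:
        raise ValueError(f"cannot parse window {text!r}; use HH:MM-HH:MM") from err
    if not (0 <= lo < hi <= 24):
        raise ValueError("window hours must satisfy 0 <= start < end <= 24")
    return lo, hi


def setup_logging(level: str = "INFO") -> None:
    """Log to stderr only; stdout is reserved for data."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
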