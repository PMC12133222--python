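"""Exceedance days under warming, and what drives the increase.

Simulates 20 summers of daily weather for a humid subtropical coastal
site, counts days whose wet-bulb meets a threshold, projects exposure
under a +4.5 °C end-century scenario with the two humidity assumptions,
and partitions the increase between warming and humidification.
"""

from humidheat import (
    ClimateParams,
    ScenarioSpec,
    apply_scenario,
    exceedance_days,
    generate_site_series,
    partition_attribution,
    threshold_sensitivity,
)

THRESHOLD = 26.0  # °C wet-bulb, upper tail of this site's summer climate
DELTA_T = 4.5     # °C, high-emissions end-century warming

series = generate_site_series(ClimateParams(n_years=20, seed=1))

base = exceedance_days(series, THRESHOLD)
print(
    f"Baseline: {base.mean_days_per_year:.2f} days/yr with wet-bulb ≥ "
    f"{THRESHOLD} °C over {base.n_years} summers (Oct–Mar)"
)

for assumption in ("constant_absolute", "constant_relative"):
    future = apply_scenario(series, ScenarioSpec(DELTA_T, assumption))
    summary = exceedance_days(future, THRESHOLD)
    print(
        f"+{DELTA_T} °C, {assumption:17s}: "
        f"{summary.mean_days_per_year:6.2f} days/yr"
    )

att = partition_attribution(series, DELTA_T, THRESHOLD)
print(
    f"\nAttribution of the increase: {100 * att.frac_tair:.0f}% warming, "
    f"{100 * att.frac_humidity:.0f}% humidification"
)

sens = threshold_sensitivity(series, THRESHOLD, offsets=(-2, -1, 0, 1, 2))
print("\nThreshold sensitivity (days/yr if the threshold is off by ±1–2 °C):")
for off, days in zip(sens.offsets, sens.exposures):
    print(f"  threshold {THRESHOLD + off:5.1f} °C → {days:6.2f} days/yr")
print(
    "\nHolding vapour density constant isolates the pure-warming effect;\n"
    "the remainder of the constant-RH increase is due to the extra\n"
    "moisture a warmer atmosphere holds."
)
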