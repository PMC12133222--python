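"""How robust is a wet-bulb threshold to measurement error?

Inverts the wet-bulb formula at the high-humidity chamber state to ask:
how wrong would the air-temperature or humidity measurements have to be
for the estimated threshold to be off by 1–2 °C?
"""

from humidheat import required_measurement_error, solve_tair_for_wet_bulb

AH = 25.0        # g m⁻³, high-humidity treatment
THRESHOLD = 31.7  # °C, species maximum wet-bulb temperature

t_base = solve_tair_for_wet_bulb(AH, THRESHOLD)
print(
    f"Base chamber state: {AH} g/m³ vapour density, "
    f"t_air = {t_base:.1f} °C → wet-bulb = {THRESHOLD} °C\n"
)

for delta_tw in (1.0, 2.0):
    dt_air, dah_pct = required_measurement_error(delta_tw, ah=AH, threshold=THRESHOLD)
    print(
        f"Wet-bulb error of {delta_tw:.0f} °C requires "
        f"{dt_air:.1f} °C in t_air  OR  {dah_pct:.1f}% in vapour density"
    )

print(
    "\nErrors of several degrees or tens of percent would be needed to\n"
    "shift the threshold by even 2 °C, so plausible instrument error\n"
    "cannot explain away the exposure estimates."
)
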