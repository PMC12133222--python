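"""Psychrometric state of humid subtropical summer air.

Builds the full psychrometric state of air at 35 °C holding the study
region's mean spring/summer vapour density (18.44 g m⁻³), and shows the
two wet-bulb estimators side by side.
"""

from humidheat import psychro_state, wet_bulb_iterative

state = psychro_state(35.0, ah=18.44)

print("Air at 35.0 °C holding 18.44 g m⁻³ of water vapour:")
for key, value in state.as_dict().items():
    print(f"  {key:24s} {value:8.2f}")

tw_iter = wet_bulb_iterative(state.t_air, state.rh)
print(f"\nStull wet-bulb:      {state.t_wet:.2f} °C")
print(f"Iterative wet-bulb:  {tw_iter:.2f} °C")
print(
    "\nThe two estimators agree within the closed form's stated ~1 °C;\n"
    "the dewpoint (21.9 °C) and relative humidity (46.7%) are the two\n"
    "equivalent ways of stating the same vapour content."
)
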