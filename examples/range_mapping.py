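"""Map exceedance across a species range and test canopy buffering.

Builds a synthetic weather grid with a latitudinal temperature gradient
and an L-shaped range polygon, maps mean exceedance days per cell,
summarises the fraction of the range exposed, and repeats the map with
a 5 °C forest-interior cooling offset.
"""

import numpy as np

from humidheat import (
    BufferingProfile,
    ClimateParams,
    apply_buffering,
    fraction_range_exposed,
    generate_grid,
    grid_exposure,
    rasterize_range_mask,
)

THRESHOLD = 26.0  # °C wet-bulb

grid, polygon = generate_grid(
    ClimateParams(n_years=3, seed=2), nlat=5, nlon=4, gradient=1.0
)
grid.mask = rasterize_range_mask(grid, polygon)
print(f"Range mask covers {int(grid.mask.values.sum())} of "
      f"{grid.mask.values.size} cells")

ge = grid_exposure(grid, THRESHOLD, season="oct_mar_summer")
print(f"\nMean exceedance days/yr (wet-bulb ≥ {THRESHOLD} °C), "
      "cold edge at top, NaN = outside range:")
print(np.round(ge.mean_days.values, 1))
frac = fraction_range_exposed(ge, min_days=1.0)
print(f"\n{frac:.0f}% of the range sees ≥ 1 exceedance day per year")

buffered = apply_buffering(grid, BufferingProfile(5.0, "preserve_absolute"))
geb = grid_exposure(buffered, THRESHOLD, season="oct_mar_summer")
fracb = fraction_range_exposed(geb, min_days=1.0)
print(
    f"With a 5 °C canopy cooling offset (vapour density preserved): "
    f"{fracb:.0f}% exposed"
)
print(
    "\nWarmer (equatorward) rows accumulate more exceedance days; the\n"
    "forest-interior offset removes most open-air exceedance, showing\n"
    "how vegetation microsites buffer lethal-heat exposure."
)
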