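# Methods

This note documents the models, conventions and numerical choices behind
`humidheat`, and what the synthetic data do and do not establish.

## Psychrometrics

All humidity conversions rest on two relations:

* **Saturation vapour pressure** (Magnus form, WMO coefficients, over
  liquid water): `e_s(t) = 6.112·exp(17.62·t/(243.12 + t))` hPa, valid
  for −40 ≤ t ≤ 60 °C. A single formula is used everywhere so the
  RH/vapour-density/dewpoint equivalences are mutually consistent.
* **Vapour density (absolute humidity)**: `ah [g m⁻³] = 216.7·e [hPa] /
  T [K]` — the ideal-gas relation with 1/R_v and unit conversions folded
  into one constant.

With these, air at 35 °C holding 18.44 g m⁻³ of vapour has RH 46.7% and
dewpoint 21.9 °C — the canonical humid-subtropical summer state used as
a consistency check throughout the tests.

**Dewpoint conventions.** Two distinct "saturation temperatures" arise
and the package keeps both, explicitly:

* `dewpoint(t, rh)` / `dewpoint_from_ah(ah, t_air)` — the standard
  *isobaric* dewpoint: cooling at constant pressure conserves vapour
  pressure, so the dewpoint is the Magnus inversion of the parcel's
  vapour pressure. Converting a vapour density to a vapour pressure
  requires the parcel's actual temperature, which is why
  `dewpoint_from_ah` takes a reference `t_air`.
* `saturation_temperature(ah)` — the temperature at which *saturated
  vapour density* equals `ah` (cooling at constant density). This is the
  point where `rh_from_absolute_humidity` reaches 100%, and it sits a
  few tenths of a degree below the isobaric dewpoint of warmer air with
  the same vapour density (21.15 vs 21.9 °C at 18.44 g m⁻³/35 °C). It is
  the natural lower bracket when inverting the wet-bulb formula at fixed
  vapour density.

Conflating the two silently shifts dewpoints by ~0.7 °C at summer
humidities, so the API forces the caller to choose.

**Wet-bulb temperature.** The pipeline uses the Stull (2011) closed-form
fit of wet-bulb temperature to (t, RH) at sea-level pressure, with the
constants transcribed exactly. Its published envelope is roughly
RH ≥ 5% and −20 ≤ t ≤ 50 °C; outside it the value is still computed but
a warning is emitted and nothing is clipped, because silent clipping on
climate grids would bias exceedance counts. The fit is accurate to a few
tenths of a degree but is not an exact solution: near saturation it can
exceed the dry-bulb temperature by up to ~0.25 °C, and the invariant
`t_dew ≤ t_wet ≤ t_air` is therefore asserted with a 0.5 °C margin. On
the envelope interior (checked on a 0.25° grid) it is strictly
increasing in both t and RH — the monotonicity that all scenario
orderings rely on. (Below ~4 °C with RH < 9% the fit is non-monotone in
RH; that corner is far outside this package's domain.)

An independent oracle, `wet_bulb_iterative`, solves the psychrometer
balance `e(t, rh) = e_s(t_w) − 6.62·10⁻⁴·P·(t − t_w)` by bracketed
root-finding in `[t_dew − 0.5, t]`. The two estimators agree within
1.0 °C over t ∈ [0, 50] × RH ∈ [20, 99] at sea level (maximum observed
difference 0.99 °C, at the hot/dry corner). The oracle exists for
testing; every analysis path uses the closed form, and pressure is fixed
at 1013.25 hPa (the fit is a sea-level regression and the target
applications are coastal/lowland).

**Root-finding.** All inversions (dewpoint from density, air temperature
or vapour density from a target wet-bulb, psychrometer balance) use
Brent's method with fixed brackets and 10⁻³ °C tolerance — unconditional
convergence and platform-reproducible results were preferred over speed.

## Species threshold from thermal endpoints

A heat-tolerance trial record qualifies as evidence of the species
maximum wet-bulb temperature (T_W-max) when, jointly, (1) the bird can no
longer hold body temperature below chamber air temperature — a tie
counts as failure, with no tolerance band — and (2) locomotor function
is compromised. Chamber environmental temperature is equated with
chamber air temperature (no radiant correction), so the endpoint
wet-bulb is computed from (t_air at endpoint, treatment vapour density)
via the RH conversion and the Stull formula.

Qualifying endpoint wet-bulbs are summarised as mean ± SD (sample SD,
n−1 denominator; "±" always means SD) with range and count. For a single
qualifying record the SD is reported as 0 with an explicit
`sd_defined=False` flag rather than NaN. Filtering is order-independent
and idempotent.

## Exceedance counting

* A day counts iff its peak daytime wet-bulb is **≥** the threshold
  (closed comparison, fixed package-wide).
* Hourly input: the wet-bulb is computed per record, restricted to the
  daytime window (default local hours [06, 18), half-open), and the
  daily maximum taken; days with no daytime records are dropped and
  counted. Daily input: each row is a (daily-max temperature, humidity)
  pair by contract, and its wet-bulb is the day's value — no attempt is
  made to reconstruct the humidity coincident with the temperature peak.
* Seasons are either calendar years or austral summers
  (October–March, labelled by the year containing October; station-style
  analyses default to the summer window, grids to calendar years). A
  season is *complete* when records cover every month of its window;
  incomplete edge seasons are excluded from the mean by default and
  includable by flag.

## Scenarios and attribution

A scenario adds a uniform increment ΔT to every record (the increment is
a plain configuration input, e.g. 2.4 or 4.5 °C for moderate- and
high-emissions end-century projections) under one of two humidity
assumptions: **constant relative humidity** (vapour density rises with
temperature) or **constant absolute humidity** (vapour density fixed, RH
falls). For ΔT > 0 the constant-absolute transform cannot supersaturate;
for ΔT < 0, RH is clipped at 100% and the clipped count logged.

Attribution compares three exposures on the same series and season:
baseline E₀, constant-absolute E_ah and constant-relative E_rh. The
warming share is `(E_ah − E₀)/(E_rh − E₀)` and the humidification share
its complement; by Stull monotonicity E₀ ≤ E_ah ≤ E_rh whenever ΔT > 0,
so both shares lie in [0, 1] and sum to 1 exactly. A degenerate
denominator (the constant-RH scenario adds no exceedance days) raises an
error rather than returning 0/0; an ordering violation (impossible under
the monotone transform, so indicative of corrupted input) flags the
result and reports NaN fractions.

Threshold sensitivity re-runs the exposure count at threshold + offset
for offsets in {−2, −1, 0, +1, +2} °C by default, modelling an over- or
underestimated species threshold.

**Measurement-error inversion.** At a base state (default: the
high-humidity trial condition — vapour density 25 g m⁻³, air temperature
solved so the wet-bulb equals the 31.7 °C threshold, i.e. ≈ 43.4 °C and
RH ≈ 41.5%), the package solves for (a) the air-temperature increase at
fixed vapour density and (b) the relative vapour-density increase at
fixed air temperature that each raise the wet-bulb by a stated amount.
Both are bracketed root-finds; the humidity bracket ends just below
saturation and a diagnostic error is raised if saturation is reached
before the target. At this base state a 2 °C wet-bulb shift requires
≈ 7.3 °C of air-temperature error or ≈ 19.6% of humidity error — the
robustness argument for wet-bulb thresholds measured in humid chambers.

## Gridded exposure and canopy buffering

Grids are xarray Datasets `tair(time, lat, lon)`, `rh(time, lat, lon)`
(read/written as NetCDF3 via the SciPy engine). Counting applies exactly
the scalar day-level rule per cell, and a property test asserts
cell-by-cell equality with the scalar path. A species range enters as a
GeoJSON polygon rasterized by cell-centre containment; cells outside the
mask carry NaN. The range fraction exposed is the percentage of in-range
cells with mean exceedance ≥ a cutoff (default 1 day yr⁻¹, evaluated on
the across-year mean), either unweighted or cos(latitude)-weighted —
both are provided because the appropriate choice depends on the grid.

Canopy buffering is a deliberately *parametric* stand-in for biophysical
microclimate models, not a heat-transfer model: inside vegetation the
air is cooler by a fixed offset (field studies commonly report midday
understory air > 5 °C cooler), with humidity following one of two rules.
`preserve_absolute` reflects the observation that vapour density is
similar inside and outside forest: RH is recomputed at the cooler
temperature and clipped at saturation, with the clipped count reported.
`preserve_relative` keeps RH and therefore strictly lowers every
wet-bulb value. Under either rule buffered exposure is ≤ unbuffered for
a non-negative offset (asserted on simulation sweeps). A convenience
routine emulates a representative-areas design: k seeded random points
per polygon, nearest-cell exposure, averaged per polygon.

## Synthetic weather and endpoint generators

The weather generator produces daily maximum temperature as a seasonal
sinusoid (peak mid-January, austral summer) plus AR(1) Gaussian
anomalies, and vapour density as correlated AR(1) anomalies around a
fixed mean; RH is *derived* from (t, ah), never drawn. This is the
simplest process with the two features the analysis is sensitive to —
day-to-day persistence (multi-day exceedance clustering) and
temperature–humidity coupling (the constant-RH vs constant-AH
contrast) — and is not a claim about any real climate. Defaults describe
a humid subtropical coastal site: summer daily max 28.0 ± 1.9 °C, vapour
density 18.44 ± 0.65 g m⁻³, peak-to-trough seasonal range 4 °C, lag-1
autocorrelation 0.6, temperature–humidity innovation correlation 0.3,
20 seasons. The sinusoid's offset is solved numerically so the
October–March mean equals `mean_tmax` exactly; series span July to June
so every October–March summer is complete. Under these defaults
wet-bulb ≥ 31.7 °C is, correctly, a non-event: the region's lethal-heat
exposure is a tail phenomenon, so scenario and attribution tests use a
threshold (26 °C) in the upper tail of the *synthetic* site's
present-day summer wet-bulb distribution, where the scenario contrast is
defined for every seed. The grid generator gives each cell an
independent series with the mean shifted by a configurable latitudinal
gradient (default 0.5 °C per degree, warm edge equatorward) and ships an
L-shaped range polygon covering a known 40% of cell centres.

The endpoint generator plants a known threshold: per bird it draws an
endpoint wet-bulb from Normal(true mean, true SD), draws an endpoint air
temperature near the heat tolerance limit (44.5 ± 1.0 °C, clamped to
[40, 46.8]), and solves for the *chamber vapour density* that realises
the drawn wet-bulb at that temperature. Solving for humidity rather than
for air temperature at fixed humidity keeps every record inside
physiological bounds (body temperature ≤ 48 °C with a positive offset
above air temperature) for arbitrary tail draws, while preserving the
round-trip property that `endpoint_wet_bulb` recovers the drawn value to
solver tolerance. Decoy records (default 25% of the qualifying count)
violate exactly one criterion each and carry `decoy_` identifiers so
exclusion is externally checkable.

All generators are pure functions of (parameters, seed); substreams are
derived from the single seed with fixed offsets, so outputs are
byte-identical across runs.

## Problem sizes and verification

The test suite checks, among others: the 18.44 g m⁻³ / 46.7% / 21.9 °C
consistency triple to printed precision; the Stull-vs-iterative sweep on
a 0.5° grid (101 × 159 points); attribution identity and exposure
ordering on 200 seeded 3-summer series; threshold recovery of
31.7 ± 1.0 °C from 8-bird tables over 500 seeds (within 3 SE in ≥ 95% of
seeds); and planted-count exactness for counting, sensitivity,
grid/scalar equivalence and range fractions. `scripts/acceptance.py`
recomputes the dewpoint of the 18.44 g m⁻³ summer state and the two
measurement-error inversions from scratch.

## Known limitations

* Sea-level pressure is assumed throughout; no altitude correction to
  the wet-bulb fit.
* No radiation or wind: wet-bulb globe temperature, operative
  temperature and solar heat loads are out of scope, so exposure
  estimates are conservative for sun-exposed animals.
* The canopy transform is parametric; it cannot capture vertical
  profiles, edge effects or transient storage that a steady-state
  canopy heat-transfer model resolves.
* The synthetic climate has no precipitation coupling, trends,
  or heatwave-specific dynamics beyond AR(1) persistence; passing tests
  demonstrate correctness of the computational chain, not skill on real
  station or reanalysis data.
* Daily-cadence exceedance uses the humidity value supplied for the day;
  if that humidity is a daily mean rather than the value coincident with
  the temperature peak, counts can be biased either way.
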