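# Methods

This note records the models, the synthetic study conditions, the numerical
choices, and what the passing tests do and do not establish.

## Water-balance hydrology

Each valid cell carries two stores: soil moisture `S ∈ [0, WHC]` (mm, bounded
by the cell's water-holding capacity) and groundwater `G ≥ 0` (mm). One
monthly step with precipitation `P`, potential evapotranspiration `E`, crop
factor `k_c`, quickflow fraction `d` and groundwater recession `r`:

    demand   = k_c · E
    AET      = min(demand, P + S)
    S'       = min(P + S − AET, WHC)
    surplus  = max(P + S − AET − WHC, 0)
    runoff   = d·surplus + r·(G + (1−d)·surplus)
    G'       = (1−r)·(G + (1−d)·surplus)

By construction `P = AET + runoff + ΔS + ΔG` exactly; the test suite checks
closure to ~1e-16 of total precipitation (the acceptance bound is 1e-6).
This two-store scheme is this package's own minimal structure in the
Thornthwaite–Mather bookkeeping lineage: it is the smallest parameter set
(two) that yields a realistic recession limb and is identifiable from a
monthly gauge. Discharge at an outlet is the masked sum of runoff volumes
over the outlet's D8 watershed divided by the actual calendar month length
(28/29/30/31 days; no sub-monthly handling).

PET uses Thornthwaite (1948): heat index `I = Σ (T_m/5)^1.514` over months
with `T_m > 0`, `PET = 16 (L/12)(N/30)(10T/I)^a(I)` with the standard cubic
`a(I)`, day length `L` defaulting to 12 h (tropical domain). The
high-temperature (>26.5 °C) polynomial branch is not implemented; the basic
form remains monotone in `T`, which is the property the projection relies
on. A zero or freezing month evaporates nothing.

Calibration is an exhaustive grid search (default 9×9 over `d, r ∈
{0.1,…,0.9}`; the demo config uses 4×4) maximizing NSE at the gauged outlet,
ties to the first candidate in grid order; the modeled:observed volume ratio
is reported alongside. Against noise-free self-simulated discharge the
search recovers the generating parameters with NSE ≥ 0.999 (exactly 1 up to
rounding); against the default 10 %-CV lognormal gauge noise, NSE ≈ 0.98.

Stores start empty and the first 24 months (configurable) are discarded, so
initialization does not contaminate statistics.

## Terrain

Depression filling is priority-flood to the exact pour level (no epsilon
gradient), idempotent and minimal. D8 directions point to the
steepest-descent neighbor with distance-weighted drops; ties break in the
fixed order E, SE, S, SW, W, NW, N, NE (ESRI codes 1…128). Cells left flat
by exact filling are resolved by a FIFO sweep from already-draining cells of
equal elevation, guaranteeing an acyclic network. Accumulation is evaluated
in topological order and is integer-exact with unit weights.

Slope is the maximum downhill gradient over the eight neighbors (consistent
with D8). LS uses the unit-contributing-area form
`LS = (A_s/22.13)^0.4 (sin θ/0.0896)^1.3` with `A_s = acc · cell_size`;
constants and exponents are overridable. A flat cell has LS = 0. Whether the
original tooling used accumulation-based or fixed slope lengths is not
recoverable; the accumulation-based form needs only quantities already
computed and is the documented choice.

## Erosion

`A = R·K·LS·C·P` per cell and year (t ha⁻¹ yr⁻¹). R comes from the annual
Modified Fournier Index through `R = a·MFI^b`, defaults a = 0.264, b = 1.50
(a published MFI→erosivity regression family; the coefficients are
configurable and every ordering/monotonicity property in the tests is
coefficient-independent). An all-zero rain year has MFI = 0 by convention.
K uses the Williams/EPIC texture + organic-carbon formulation, which maps
coarse organic-rich soils to the "resistant" band (≈0.05–0.2) and silty
carbon-poor soils to the "easily eroded" band (≥0.4). Watershed yield is
`SDR · Σ A · cell_area`, with a lumped sediment-delivery ratio (default 0.1)
standing in for routed in-channel accumulation; it rescales totals without
affecting any fractional change. SCS curve-number runoff
(`S = 25400/CN − 254`, initial abstraction 0.2 S) is computed as a
diagnostic channel only; the annual RUSLE yield is the headline output. No
event-scale (MUSLE) variant and no nutrient accounting are included.

Default cover factors: k_c 1.0 (forest), 0.85 (grassland), 0.90 (cropland),
0.40 (bare), 1.05 (water); C 0.02 (forest), 0.05, 0.25, 0.45, 0.0 (water).
The forest C of 0.02 sits inside the published 0.001–0.05 band for dense
tropical forest and puts the current-vs-natural yield ratio near the
order of magnitude reported for real degraded tropical catchments (~4 in
the packaged runs). Cells converted by deforestation form their own class
carrying the weighted average of the non-forest factors (weights 0.5
grassland / 0.3 cropland / 0.2 bare).

## Climate scenarios

Monthly climatologies are per-month arithmetic means over a year window
(default full cube; the canonical windows are 1975–2005 and 2065–2095, both
configurable; a running-window variant labels each 31-year position by its
inclusive year pair). Temperature deltas are **signed** differences
future − baseline — a magnitude-only reading would silently flip cooling and
break the round-trip identity (applying deltas computed from two
climatologies must reproduce the future climatology). Precipitation ratios
divide by `max(baseline, 1 mm/month)` and clamp at 10: the delta method is
undefined at a zero baseline and unbounded ratios are physically
meaningless. Identity deltas (add 0, multiply 1) leave a cube bit-identical.
Seasons default to wet Nov–Apr / dry May–Oct (Southern-Hemisphere
convention), configurable. Ensemble summaries are elementwise means or
medians; no quantile mapping or dynamical downscaling is attempted.

## Land-use ladder

Nine configurations: biome (all eligible open land to forest — the synthetic
stand-in for a natural-vegetation map), afforest 50/25/10 %, the 2000
baseline, deforest 10/25/50/100 %. Suitability rank-normalizes slope and
road distance to [0,1] (average ranks for ties; a single eligible cell maps
to 0.5) and combines them with weights (default 0.5/0.5): deforestation
scores flat + road-near forest high, afforestation the complements. Targets
convert the top `round(f·n_eligible)` cells **grid-wide** (the island-wide
reading: per-region converted fractions can differ from the target), ties at
the cut broken by row-major index. Because every target uses one frozen
surface, converted sets nest monotonically along the ladder, which (with
C(forest) ≤ C(non-forest)) forces present-day yields to be non-decreasing
from biome to full deforestation.

## Flow→sediment projection

Future sediment is not re-run through the erosion chain. Per watershed and
land-use configuration, present-day annual yields are regressed (OLS) on
annual flow statistics; the baseline-2000 fit selects the statistic with the
highest r² (ties to annual max, which generally wins) and that single
statistic is reused for every configuration of the same watershed — one
relationship family per gauge. Without pinning, near-tied r² values let
adjacent ladder steps project from different statistics and produce spurious
1–3 % ordering inversions. Projected yields `max(0, a + b·stat)` are clamped
at zero with a logged warning (linear extrapolation under strong flow
declines can cross zero; physical yields cannot). Calendar years (not water
years) group the statistics; partial leading/trailing years are dropped.

Because OLS with an intercept makes fitted means equal observed means, an
identity GCM ensemble reproduces the present-day column of the scenario grid
to floating-point rounding (discharge itself is bit-identical; the fractional
changes agree to ~1e-15 relative, asserted at 1e-9).

The scenario grid reports, per (land use × climate × region), the mean
annual yield, its fractional change relative to the (2000 land use × present
climate) cell — which therefore reads exactly 1.0 — and a companion
`fractional_change_vs_natural` column referenced to the biome configuration,
plus the mean and across-GCM standard deviation. One regression per
watershed (rather than one global fit) is used because the regions differ
climatically.

## Synthetic study conditions

The generators define the study conditions; their defaults are fixed once:

- **Terrain**: smoothed Gaussian random field (σ ≈ min(n)/10 cells) plus a
  ramp rising from all edges (relief 60 m), depression-filled. Each quadrant
  (region) drains to its own maximum-accumulation edge cell, which becomes
  the region's gauged outlet; watershed masks of distinct edge outlets are
  provably disjoint.
- **Regions**: a quadrant partition standing in for the four catchments —
  NE wettest to SW driest. Monthly precipitation means (mm/month, wet/dry):
  NE 300/100, NW 230/40, W 170/25, SW 110/15; wet season Nov–Apr.
- **Precipitation**: gamma per cell-month (shape 4), scaled by a shared
  per-(year, region) lognormal wetness factor with unit mean and CV 0.25.
  The shared factor supplies the spatially coherent interannual variability
  of real monthly climate (region-wide wet and dry years); without it,
  annual maximum flow and annual erosivity share almost no year-to-year
  variance and the flow→sediment regressions the projection depends on have
  near-zero explanatory power. With it, their r² is ≈ 0.9, comparable to
  what gauge-based studies report. `precip_shape = ∞` collapses both noise
  sources to the exact seasonal means.
- **Temperature**: regional mean (24–26.5 °C) + 3 °C seasonal cosine peaking
  in January + 0.5 °C Gaussian noise.
- **Soils**: smoothed fields — WHC 50–200 mm, exp-normal texture shares
  normalized to 100 %, organic carbon 0.5–4 %; hydrologic soil groups from
  sand/clay thresholds (A ≥ 55 % sand … D ≥ 40 % clay).
- **Roads**: three random cross-grid polylines; only the Euclidean distance
  field matters. Forest occupies the top-scoring fraction of land by
  slope + road-distance rank (plus 10 % noise), emulating
  accessibility-driven deforestation history; 2 % of cells along the
  highest-accumulation paths are water.
- **GCM ensembles**: per member, one uniform warming offset (B1 1–2 °C,
  A1b 1.5–3 °C, A2 2–4 °C — small/moderate/large) and seasonal
  precipitation scalings (wet −5…+10 %, dry −20…−5 %), applied to the base
  series and relabelled to the future window.
- **Gauge**: multiplicative lognormal noise with unit mean (default CV 0.1)
  on self-simulated discharge.

What the generators do **not** emulate: real geography and soil taxonomy,
orographic precipitation gradients, tropical-cyclone extremes, serially
correlated droughts, land-cover dynamics between scenario snapshots, and any
in-channel sediment storage. Passing tests therefore establish internal
consistency, correct numerics, and the qualitative mechanism ordering — not
calibrated predictions for any real catchment.

## Problem sizes and determinism

The packaged demo runs 16×16 cells × 20 years × 3 GCMs (seconds); the
acceptance script runs a 32×32/30-year balance audit plus a 20×20/31-year/3-
GCM full grid; the ladder-ordering test repeats a 16×16/31-year/2-GCM grid
over ten seeds. These sizes give stable statistics (regression r² ≈ 0.9,
across-GCM sd ≪ across-ladder spread) while keeping the whole suite fast.
A single integer seed fans out to per-stage streams via
`SeedSequence([seed, stage])`; every stage is a pure function of its inputs
and seed, so identical configurations produce identical outputs.

## Known limitations

- The hydrological scheme is a monthly two-parameter stand-in; it has no
  channel routing delay, so basin discharge responds to runoff within the
  generating month.
- The SDR is lumped and scale-free; absolute yields are only meaningful
  relative to each other.
- Regression-based future sediment inherits OLS extrapolation risk under
  strong drying; the zero clamp is a blunt guard.
- Erosivity coefficients (a, b) are a stand-in family; absolute R values
  should not be compared against gauge-calibrated erosivity maps.
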