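# Methods

This note documents the reconstruction model, its parameters, the
synthetic data generator, and the numerical and design choices the
implementation makes where the procedure was genuinely open.

## Model overview

The package reconstructs the annual soil-surface nitrogen balance —
inputs (mineral fertilizer, animal manure, atmospheric deposition,
biological fixation) minus outputs (harvested-crop removal, grass removal
by grazing/cutting, a small forest removal term) — per grid cell over
1850–2019, for six land types: cropland, pasture, forest, semi-natural
vegetation, non-vegetated and urban land.  The soil-surface convention
excludes volatilization losses during manure management from the applied
amounts; their later re-deposition is part of the deposition term.

The central difficulty is combining sources with different support:
gridded snapshots around 2000, a decadal gridded land-use history,
country×year statistics from 1961, global trends before that, and a
handful of snapshot years in the 19th century.  The pipeline resolves
this with two recurring devices:

* **Ratio referencing.** A year-2000 spatial pattern is carried through
  time by a temporal ratio anchored at 2000 (land use, crop areas) or
  1961 (pre-statistical extensions of fertilizer, manure, crop ratios).
* **Harmonization.** After gridding, a single country-year scalar rescales
  each country's cells so their sum matches the authoritative table
  exactly; relative spatial structure is preserved.

All internal arithmetic uses extensive units (kg or ha per cell), so
conservation checks are exact; per-hectare rates appear only at I/O
boundaries.  Cell areas come from the spherical band formula per latitude.

## Stage-by-stage specifics

**Land use.** Decadal history values are linearly interpolated to annual;
the two years past the history's end hold its last value.  Cell-level
ratios to 2000 scale the snapshot; country harmonization uses per-year
ratios for 1961–2019, the 1961 ratio before, and — for countries whose
series only start in 1992 — the 1992 ratio for all earlier years.
Countries reported as a merged pair until a split year share one ratio
over the combined footprint.  Where the harmonized cropland+pasture area
exceeds the physical cell area, the excess is removed pro-rata from the
two components and spread equally over the country's cells with spare
capacity.  Because moved mass keeps its donor composition, cropland and
pasture country totals are conserved *simultaneously*, so no further
re-pinning is needed (a rescale-based re-pin could re-violate capacity).
The non-agricultural residual is split by static year-2000 land-cover
proportions; cells whose land-cover fractions sum to zero assign the
residual to semi-natural vegetation.

**Crops.** The 17 non-fodder crops follow the cropland dynamics cellwise
and are pinned per (country, crop, year); the 6 fodder categories come
from a country-level source with gap-filling: a mapped neighbour's
fodder/cropland ratio where available, otherwise the pooled 1992 ratio of
the Eastern-European donor countries, both applied to the missing
country's own cropland.  Fodder areas before 1961 use each country's 1961
fodder/cropland ratio.  Production before 1961 follows wheat: snapshot
wheat yields (1850/1909/1934/1960) are interpolated linearly, countries
absent from the yield source get the reporting countries' mean, wheat
production = yield × harvested area, and every other crop's 1961
production is scaled by the wheat trajectory.  Gridding of production
uses static year-2000 spatial weights; a country whose weights vanish
falls back to a uniform split over its cropland cells.

**Fertilizer.** Nothing before 1920; a linear bridge 1920–1924; the
global production trend 1925–1960 anchored so its final year meets the
country's 1961 statistic (the trend source ends in 1960, so we anchor
its last value to the 1961 splice point for continuity).  Missing series
before 1992 take the donor pool's total dynamics anchored at 1992;
merged pairs are split by their shares at the split year.  2014/15
crop-group amounts over harvested areas give per-crop rates (group rate
assigned to each member crop); fodder and pasture take the grassland
rate; countries outside the rate source take the pooled member rates,
fixed at 2014/15 rather than recomputed per year.  A country-year
adjustment scalar pins the gridded total; the cropland/pasture split is
either the rate-based one or a rescale to external shares (identical
country totals by construction).

**Manure.** Country applied/left amounts over the production-grid
aggregate give two ratios per country-year (1961 ratios before 1961;
production years outside 1860–2014 are edge-padded).  The cap (default
250 kg N per hectare of agricultural area, the upper end of the
permissible 170–250 range) applies to applied+left jointly, before the
cropland/pasture split; excess moves through expanding 8-neighbour rings
restricted to the same country's agricultural cells, donors processed in
row-major order, excess removed pro-rata from both components.  The
uniform distribution splits a cell's applied manure pro-rata to its
cropland and pasture areas; the share-based distribution rescales the
country's cropland fraction to external shares using a water-filling
rule (scale up to each cell's applied ceiling) so per-cell totals stay
non-negative and country totals exact.  Manure to pasture adds the
left-on-pasture term.

**Deposition and fixation.** Coarse monthly deposition is downscaled by
nearest-neighbour in cell-centre distance, summed to annual, and held at
the final source year (2014) afterwards; the sea fraction's deposition is
discarded.  Per land type, deposition is the total rate times the type's
area.  Fixation is area-based — pasture 5, temperate forest 16, boreal
forest 1.77 (boreal status by country list, not latitude), semi-natural
2.7, soybean 80, pulses 50 kg N ha⁻¹ yr⁻¹ — except fodder crops, whose
per-kg-product rates are derived per (country, category) as pooled
fixation over pooled production from the country-level source (the rate
definition carries no explicit country index in its original form; the
country-level pooling is this package's reading, since the source data
are country tables).

**Removals and assembly.** Crop removal is production × N content (kg
t⁻¹).  Pasture removal, `C·(Inp_past − losses·Man_past)`, is floored at
zero — numerically the loss-adjusted balance can go negative, physically
removal cannot.  Negative *surpluses* by contrast are retained: a soil
balance can be negative.  The 16 members share everything except the four
choice axes; member ordering puts the fertilizer axis slowest and the
pasture scenario fastest, recorded in the run manifest.

## Synthetic generator

The generator emulates the shapes, units, temporal coverage and gap
patterns of the real sources on a toy grid (default 20×20 half-degree
cells, 8 countries, a sea margin): Voronoi country shapes; spatial fields
as Gaussian noise low-pass filtered and squashed to valid ranges (smooth
autocorrelation without external data); country land-use trends as
piecewise-linear decadal random walks normalised to 1 in 2000; fertilizer
as a logistic rise-then-plateau; deposition on an integer-factor coarser
grid with a seasonal cycle; statistical tables as grid aggregates times
smooth multiplicative noise in [0.8, 1.25], keeping harmonization ratios
in a realistic band.  Gap patterns (series missing before 1992, merged
reporting pairs) are applied per the registry and can be switched off.
A single master seed spawns per-component substreams, so bundles are
bit-reproducible and components individually stable.

Default intensity scales (cropland ≤ 0.35 and pasture ≤ 0.25 of a cell,
peak fertilizer 60 kg N per agricultural ha, manure production 25 and
deposition 8 kg N ha⁻¹ yr⁻¹) were chosen once as order-of-magnitude
realistic for intensive European agriculture; the generator aims at
structural, not statistical, realism.  What passing tests show is that
the *machinery* — interpolation, harmonization, redistribution,
downscaling, budget assembly — is correct and conservative; they say
nothing about how faithful any particular real-world input is.

**Known-truth mode** inverts the pipeline's deterministic maps from a
chosen gridded truth: snapshots are the truth's year-2000 slice, country
tables its exact aggregates, gaps disabled, manure production
proportional to agricultural area so the cap never binds, and cropland
and pasture share one temporal trend per country so the implied
cropland/pasture splits are time-constant (the share records only reach
back to 1961; constant splits make the share-based variants exactly
invertible too).  The truth fields themselves are computed in the
generator by direct per-cell algebra, independent of the pipeline's
generic machinery; the end-to-end test requires recovery to 1e-6
relative (observed: ~1e-15).

## Numerical choices and degenerate inputs

* Zero-denominator ratios (temporal reference, harmonization,
  production back-cast) become 1 — the value is carried unchanged — with
  a warning; no mass is invented.
* A positive country table over a zero gridded field is a hard error for
  areas and manure (mass cannot be placed); for fertilizer the target is
  spread uniformly over the country's agricultural area (split pro-rata
  cropland/pasture), logged.
* Redistribution's equal-split loop clips at each receiver's spare
  capacity and re-splits, which terminates in at most n rounds; ring
  search expands to the grid diameter and errors if mass remains.
* Conservation tolerances in tests are 1e-9 relative; the water-filling
  bisection runs 80 iterations with a final polish on unclipped cells.
* Missing table entries inside the statistical era (beyond the modelled
  gap patterns) carry the nearest earlier ratio forward; leading gaps
  take the first reported value.

## Problem sizes

The shipped configuration — 400 cells, 8 countries, 170 years, 23 crops,
16 members — runs the full pipeline in a few seconds and the whole test
suite in well under a minute; the structure is O(years × cells) per crop
and scales linearly in members beyond the shared components.

## Known limitations

* The generator's statistical realism stops at orders of magnitude; no
  attempt is made to mimic FAOSTAT API formats or real spatial
  covariance.
* Crop calendars, multi-cropping (beyond a warning at >2× cropland),
  fertilizer trade/timing, livestock-count modelling and wet/dry
  deposition splits are out of scope.
* Region masks are synthetic (country splits and latitude bands);
  real administrative or basin shapefile ingestion is not implemented.
* Continental headline magnitudes depend on the real external databases
  and are not reproducible from synthetic inputs; the package's claims
  are about the reconstruction machinery, coefficients and worked
  examples.
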