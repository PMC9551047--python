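"""Generate a synthetic input bundle and look at what it contains.

The bundle stands in for the external databases a real reconstruction
would consume: a year-2000 land-use snapshot, a decadal land-use history,
country statistical tables for 1961-2019 (with realistic reporting gaps),
crop patterns, fertilizer and manure records, and coarse monthly
deposition.  Everything is deterministic in the seed.
"""

import numpy as np

import nsurplus as ns

cfg = ns.SyntheticConfig(seed=42)
bundle = ns.generate_bundle(cfg)

grid = bundle.grid
print(f"grid: {grid.n_lat} x {grid.n_lon} cells at {grid.resolution} deg, "
      f"{int(grid.is_land.sum())} land cells, {len(grid.countries)} countries")
print(f"cell areas span {grid.cell_area.min():,.0f} - {grid.cell_area.max():,.0f} ha "
      "(spherical bands shrink northwards)")

crop_frac = bundle.snapshot_cropland.sum() / grid.cell_area.sum()
print(f"year-2000 cropland covers {100 * crop_frac:.1f}% of the domain")

fert = bundle.fao_fertilizer.df
print(f"country fertilizer table: {fert.shape[0]} years x {fert.shape[1]} countries, "
      f"{int(fert.isna().sum().sum())} missing entries "
      "(series starting in 1992, merged reporting)")

u = sorted(bundle.registry.missing_before_1992)[0]
print(f"country {u} reports nothing before 1992: "
      f"1991 -> {fert.at[1991, u]}, 1992 -> {fert.at[1992, u]:,.0f} kg N")
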