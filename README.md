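# nsurplus

Long-term annual **soil-surface nitrogen surplus** on a regular lat/lon
grid, 1850–2019, for agricultural *and* non-agricultural soils, with a
16-member ensemble spanning methodological uncertainty.

Surface waters across Europe still show nitrate levels above regulatory
thresholds decades after mitigation began, largely because of *legacy
nitrogen* — N that accumulated in soils and groundwater over the past
century.  Quantifying that legacy needs spatially resolved N budgets
reaching far further back than the statistical era.  This package
implements such a reconstruction as a tested, reusable pipeline: it fuses
a year-2000 gridded land-use/crop snapshot, a decadal land-use history,
country statistical tables (1961–2019), industry fertilizer rates, a
gridded manure-production history, coarse monthly atmospheric deposition
and snapshot wheat yields into annual gridded budget components, and it
ships a seeded synthetic generator that emulates all of those sources so
the full pipeline is runnable and verifiable at desk scale.

## The budget

For each grid cell *i* and year *y* (all terms kg N yr⁻¹):

```
Surp_soil = Surp_agri + Surp_NonAgri
Surp_agri = (Inp_cr − Rem_cr) + (Inp_past − Rem_past)
Inp_x     = FERT_x + MAN_x + DEP_x + BNF_x          x ∈ {cr, past}
Surp_NonAgri = (DEP_For + BNF_For − Rem_For) + (DEP_NatVeg + BNF_NatVeg)
             + DEP_NonVeg + DEP_Urban
```

Crop removal uses crop-specific N contents (e.g. wheat 20, maize 13,
soybean 45 kg N t⁻¹); pasture removal follows a nitrogen-use-efficiency
rule `Rem_past = C·(Inp_past − losses·MAN_past)`; forest removal is 2% of
forest deposition.  Country statistics are pinned exactly: every gridded
stage re-aggregates to its country×year table, and two mass-preserving
redistribution algorithms keep agricultural area within the physical cell
area and manure application under a 170–250 kg ha⁻¹ cap.

The ensemble crosses four binary choices — fertilizer partitioning
(industry rates vs. external cropland/pasture shares), manure source (two
statistical compilations), manure distribution (uniform by area vs.
external shares), pasture removal scenario (NUE 0.6 with 20% manure
losses vs. 0.4/0.5 east/west without) — into 16 members, written as
`N_sur_total_kg_ha_grid_1850_2019_method_01..16_v1.0.nc`.

## Worked example

```python
import nsurplus as ns

bundle = ns.generate_bundle(ns.SyntheticConfig(seed=42))
components, results = ns.build_ensemble(bundle)
stats = ns.summarize_ensemble(
    [r.surp_soil.to_per_ha_grid(bundle.grid) for r in results])
land = bundle.grid.is_land
for year in (1900, 1960, 1990, 2015):
    t = year - 1850
    print(year, round(stats["mean"].values[t, land].mean(), 1),
          (round(stats["min"].values[t, land].mean(), 1),
           round(stats["max"].values[t, land].mean(), 1)))
```

prints (seed 42, default 20×20 half-degree toy grid):

```
1900 10.0 (9.6, 10.5)
1960 13.1 (12.2, 14.0)
1990 21.5 (19.7, 23.1)
2015 22.9 (20.7, 24.8)
```

i.e. the mean total surplus in kg N per hectare of grid area, with the
ensemble min–max range: low and stable in the pre-industrial era, rising
steeply with post-war fertilizer use, flattening after 1990.  The
`examples/` directory has one short script per capability (input
generation, ensemble run, regional aggregation, known-truth recovery,
evaluation against a reference), and `nsurplus generate|run|evaluate`
exposes the same steps as a CLI.

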