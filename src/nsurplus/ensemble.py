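"""Budget assembly, the 16-member ensemble, and the pipeline driver.

The soil-surface surplus is assembled per land type from the component
fields (inputs minus removals, Surp_soil = Surp_agri + Surp_NonAgri).  The
ensemble spans a 2x2x2x2 Cartesian product of methodological choices —
fertilizer partitioning, manure source, manure distribution, pasture
removal scenario — with the fertilizer axis slowest and the pasture
scenario fastest in the member ordering (member 1..16).  Components that
do not depend on an axis (land use, crops, deposition, fixation, crop and
forest removal) are computed once and shared.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import aggregate_to_regions
from .coefficients import PASTURE_SCENARIOS, CoefficientSet, DEFAULT_COEFFICIENTS
from .crops import CropAreas, CropProduction, reconstruct_crops
from .deposition_bnf import (BNFResult, DepositionResult, allocate_deposition,
                             compute_bnf, derive_fodder_bnf_rates, downscale_deposition)
from .fertilizer import (FertilizerApproach, FertilizerResult,
                         complete_country_fertilizer, derive_ifa_rates,
                         fill_country_shares, grid_and_adjust, partition_fertilizer)
from .fields import AnnualField, CountryYearTable
from .grid import GridSpec, RegionMask
from .landuse import LanduseResult, interpolate_decadal, reconstruct_landuse
from .manure import (ManureDistribution, ManureResult, ManureSource,
                     cap_and_redistribute, compute_country_ratios,
                     distribute_to_cropland_pasture, grid_manure, pad_production)
from .nc_io import surplus_filename, write_annual_field, write_region_csv
from .registry import FODDER_CROPS, NON_FODDER_CROPS
from .removal import crop_removal, forest_removal, pasture_removal
from .synthetic import InputBundle, SyntheticConfig, generate_bundle


@dataclass(frozen=True)
class EnsembleVariant:
    """One combination of the four methodological axes (member 1..16)."""

    index: int
    fertilizer_approach: FertilizerApproach
    manure_source: ManureSource
    manure_distribution: ManureDistribution
    pasture_scenario: str

    def label(self) -> str:
        return (f"{self.index:02d}:{self.fertilizer_approach.value}"
                f"/{self.manure_source.value}/{self.manure_distribution.value}"
                f"/{self.pasture_scenario}")


def ensemble_variants() -> list[EnsembleVariant]:
    """The 16 members: fertilizer axis slowest, pasture scenario fastest."""
    out = []
    axes = product(FertilizerApproach, ManureSource, ManureDistribution, ("S1", "S2"))
    for k, (fa, ms, md, ps) in enumerate(axes, start=1):
        out.append(EnsembleVariant(k, fa, ms, md, ps))
    return out


@dataclass
class SurplusResult:
    """Per-member budget fields (kg per cell per yr) plus audit components."""

    variant: EnsembleVariant
    surp_cr: AnnualField
    surp_past: AnnualField
    surp_agri: AnnualField
    surp_for: AnnualField
    surp_natveg: AnnualField
    surp_nonveg: AnnualField
    surp_urban: AnnualField
    surp_nonagri: AnnualField
    surp_soil: AnnualField
    inp_cr: AnnualField
    inp_past: AnnualField
    rem_cr: AnnualField
    rem_past: AnnualField
    rem_for: AnnualField


@dataclass
class PipelineComponents:
    """Everything computed once and shared across ensemble members."""

    grid: GridSpec
    landuse: LanduseResult
    crop_areas: CropAreas
    crop_production: CropProduction
    nfer_soil: CountryYearTable
    fertilizer: dict[FertilizerApproach, FertilizerResult]
    manure: dict[tuple[ManureSource, ManureDistribution], ManureResult]
    deposition: DepositionResult
    bnf: BNFResult
    rem_cr: AnnualField
    rem_for: AnnualField


def run_components(bundle: InputBundle,
                   coefficients: CoefficientSet = DEFAULT_COEFFICIENTS) -> PipelineComponents:
    """Run every axis-independent stage of the pipeline on a bundle."""
    grid, registry, cfg = bundle.grid, bundle.registry, bundle.config

    # --- land use ------------------------------------------------------------
    hyde_cr = AnnualField("A_HYDE_cr", "ha", cfg.year0, interpolate_decadal(
        bundle.hyde_decadal_years, bundle.hyde_decadal_cropland,
        bundle.hyde_annual_years, bundle.hyde_annual_cropland,
        cfg.year0, cfg.year1))
    hyde_pa = AnnualField("A_HYDE_past", "ha", cfg.year0, interpolate_decadal(
        bundle.hyde_decadal_years, bundle.hyde_decadal_pasture,
        bundle.hyde_annual_years, bundle.hyde_annual_pasture,
        cfg.year0, cfg.year1))
    landuse = reconstruct_landuse(
        grid, registry, bundle.snapshot_cropland, bundle.snapshot_pasture,
        hyde_cr, hyde_pa, bundle.fao_cropland, bundle.fao_pasture,
        bundle.glc_fractions)

    # --- crops ---------------------------------------------------------------
    crop_areas, crop_production = reconstruct_crops(
        grid, registry, landuse.cropland, bundle.monfreda_areas,
        bundle.monfreda_production, bundle.fao_crop_areas, bundle.fao_production,
        bundle.einarsson_fodder_areas, bundle.einarsson_fodder_production,
        bundle.owd_yields)

    # --- fertilizer ----------------------------------------------------------
    nfer_soil = complete_country_fertilizer(
        bundle.fao_fertilizer, bundle.holland_global, registry)
    areas_2015 = bundle.fao_crop_areas.df.loc[2015].unstack().fillna(0.0)
    grass_2015 = pd.Series({
        int(u): float(bundle.fao_pasture.df.at[2015, int(u)]) +
        float(bundle.einarsson_fodder_areas.df.get((int(u), "temporary_grassland"),
                                                   pd.Series(dtype=float)).get(2015, 0.0))
        for u in grid.countries})
    rates = derive_ifa_rates(bundle.ifa_amounts, areas_2015, grass_2015, registry)
    fer_cr, fer_past = grid_and_adjust(
        rates, crop_areas.non_fodder, crop_areas.fodder, landuse.pasture,
        landuse.agricultural, nfer_soil, grid)
    fert_share = fill_country_shares(
        bundle.einarsson_fert_cropland_share, registry,
        [int(u) for u in grid.countries])
    fertilizer = {
        a: partition_fertilizer(fer_cr, fer_past, a, grid, landuse.cropland,
                                landuse.pasture, fert_share)
        for a in FertilizerApproach}

    # --- manure --------------------------------------------------------------
    prod = pad_production(bundle.zhang_production, cfg.year0, cfg.year1).to_per_cell(grid)
    man_share = fill_country_shares(
        bundle.einarsson_manure_cropland_share, registry,
        [int(u) for u in grid.countries])
    manure: dict[tuple[ManureSource, ManureDistribution], ManureResult] = {}
    source_tables = {
        ManureSource.FAOSTAT: (bundle.fao_manure_applied, bundle.fao_manure_left),
        ManureSource.EINARSSON: (bundle.einarsson_manure_applied, bundle.einarsson_manure_left),
    }
    for source, (t_app, t_left) in source_tables.items():
        r_app, r_left = compute_country_ratios(t_app, t_left, prod, grid)
        g_app = grid_manure(r_app, prod, grid)
        g_left = grid_manure(r_left, prod, grid)
        g_app, g_left = cap_and_redistribute(
            g_app, g_left, landuse.agricultural, grid, coefficients.manure_cap)
        for dist in ManureDistribution:
            manure[(source, dist)] = distribute_to_cropland_pasture(
                g_app, g_left, landuse.cropland, landuse.pasture, grid,
                source, dist, man_share)

    # --- deposition & fixation ----------------------------------------------
    dep_rate = downscale_deposition(
        bundle.deposition_monthly, bundle.deposition_lat, bundle.deposition_lon,
        bundle.deposition_year0, grid, cfg.year0, cfg.year1)
    deposition = allocate_deposition(dep_rate, landuse, grid)
    fodder_rates = derive_fodder_bnf_rates(
        bundle.einarsson_fodder_bnf.df, bundle.einarsson_fodder_production.df)
    fodder_pro = {c: crop_production.gridded[c] for c in FODDER_CROPS
                  if c in crop_production.gridded}
    bnf = compute_bnf(landuse, crop_areas.non_fodder, fodder_pro, fodder_rates,
                      coefficients, registry, grid)

    # --- shared removals -----------------------------------------------------
    rem_cr = crop_removal({c: crop_production.gridded[c] for c in NON_FODDER_CROPS
                           if c in crop_production.gridded}, coefficients)
    rem_for = forest_removal(deposition.dep_for, coefficients)
    return PipelineComponents(
        grid=grid, landuse=landuse, crop_areas=crop_areas,
        crop_production=crop_production, nfer_soil=nfer_soil,
        fertilizer=fertilizer, manure=manure, deposition=deposition, bnf=bnf,
        rem_cr=rem_cr, rem_for=rem_for)


def assemble_budget(
    components: PipelineComponents,
    variant: EnsembleVariant,
    registry,
    coefficients: CoefficientSet = DEFAULT_COEFFICIENTS,
) -> SurplusResult:
    """Per-land-type budget identities for one ensemble member."""
    fert = components.fertilizer[variant.fertilizer_approach]
    man = components.manure[(variant.manure_source, variant.manure_distribution)]
    dep = components.deposition
    bnf = components.bnf
    for f in (fert.fer_cr, man.man_cr, dep.dep_cr, bnf.bnf_cr):
        if f.values.shape != components.rem_cr.values.shape or f.year0 != components.rem_cr.year0:
            raise ValueError("component grids/year ranges are mismatched")
    inp_cr = fert.fer_cr + man.man_cr + dep.dep_cr + bnf.bnf_cr
    inp_past = fert.fer_past + man.man_past + dep.dep_past + bnf.bnf_past
    rem_past = pasture_removal(inp_past, man.man_past,
                               PASTURE_SCENARIOS[variant.pasture_scenario],
                               registry, components.grid)
    surp_cr = inp_cr - components.rem_cr
    surp_past = inp_past - rem_past
    surp_agri = surp_cr + surp_past
    surp_for = dep.dep_for + bnf.bnf_for - components.rem_for
    surp_natveg = dep.dep_natveg + bnf.bnf_natveg
    surp_nonveg = dep.dep_nonveg
    surp_urban = dep.dep_urban
    surp_nonagri = surp_for + surp_natveg + surp_nonveg + surp_urban
    surp_soil = surp_agri + surp_nonagri

    def _tag(f: AnnualField, name: str) -> AnnualField:
        return f.like(f.values, name=name)

    return SurplusResult(
        variant=variant,
        surp_cr=_tag(surp_cr, "Surp_cr"), surp_past=_tag(surp_past, "Surp_past"),
        surp_agri=_tag(surp_agri, "Surp_agri"), surp_for=_tag(surp_for, "Surp_For"),
        surp_natveg=_tag(surp_natveg, "Surp_NatVeg"),
        surp_nonveg=_tag(surp_nonveg, "Surp_NonVeg"),
        surp_urban=_tag(surp_urban, "Surp_Urban"),
        surp_nonagri=_tag(surp_nonagri, "Surp_NonAgri"),
        surp_soil=_tag(surp_soil, "Surp_soil"),
        inp_cr=_tag(inp_cr, "Inp_cr"), inp_past=_tag(inp_past, "Inp_past"),
        rem_cr=components.rem_cr, rem_past=_tag(rem_past, "Rem_past"),
        rem_for=components.rem_for)


def build_ensemble(
    bundle: InputBundle,
    coefficients: CoefficientSet = DEFAULT_COEFFICIENTS,
    members: list[int] | None = None,
) -> tuple[PipelineComponents, list[SurplusResult]]:
    """Shared components once, then one budget per requested member."""
    components = run_components(bundle, coefficients)
    results = [assemble_budget(components, v, bundle.registry, coefficients)
               for v in ensemble_variants()
               if members is None or v.index in members]
    return components, results


def summarize_ensemble(fields: list[AnnualField]) -> dict[str, AnnualField]:
    """Cellwise mean/sd/min/max over ensemble members."""
    stack = np.stack([f.values for f in fields])
    f0 = fields[0]
    return {
        "mean": f0.like(stack.mean(axis=0), name="mean"),
        "sd": f0.like(stack.std(axis=0, ddof=0), name="sd"),
        "min": f0.like(stack.min(axis=0), name="min"),
        "max": f0.like(stack.max(axis=0), name="max"),
    }


def synthetic_region_mask(grid: GridSpec, scheme: str) -> RegionMask:
    """Region schemes on the toy grid: countries, sub-country blocks, basins."""
    if scheme in ("NUTS0", "nuts0"):
        return RegionMask.from_countries(grid, "NUTS0")
    if scheme in ("NUTS1", "nuts1"):
        # split each country into a northern and a southern half
        region = np.zeros(grid.n_cells, dtype=int)
        for u in grid.countries:
            cells = grid.cells_of(int(u))
            rows = cells // grid.n_lon
            south = rows > np.median(rows)
            region[cells[~south]] = 2 * int(u) - 1
            region[cells[south]] = 2 * int(u)
        return RegionMask("NUTS1", region)
    if scheme in ("basins", "basin"):
        # latitude bands crossing countries, like river basins crossing borders
        rows = np.arange(grid.n_cells) // grid.n_lon
        region = (rows // max(grid.n_lat // 4, 1) + 1).astype(int)
        region[~grid.is_land] = 0
        return RegionMask("basin", region)
    raise ValueError(f"unknown region scheme {scheme!r}")


def run_pipeline(
    config: SyntheticConfig,
    out_dir: str | Path,
    coefficients: CoefficientSet = DEFAULT_COEFFICIENTS,
    members: list[int] | None = None,
    regions: tuple[str, ...] = ("NUTS1", "basins"),
) -> dict:
    """Generate inputs, run the ensemble, write NetCDF + CSV + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    grid = bundle.grid
    components, results = build_ensemble(bundle, coefficients, members)
    per_ha = []
    for res in results:
        f = res.surp_soil.to_per_ha_grid(grid)
        f = f.like(f.values, name="N_surplus")
        f.mask = np.broadcast_to(~grid.is_land, f.values.shape)
        write_annual_field(
            out / surplus_filename(config.year0, config.year1, res.variant.index),
            f, grid, long_name="total soil-surface N surplus")
        per_ha.append(res)
    area = AnnualField("area", "ha", config.year0, grid.cell_area[None, :])
    for scheme in regions:
        mask = synthetic_region_mask(grid, scheme)
        tables = [aggregate_to_regions(r.surp_soil, mask, grid, normalizer=area)
                  for r in results]
        stack = np.stack([t.to_numpy() for t in tables])
        long = tables[0].stack().reset_index()[["region_id", "year"]]
        long["mean"] = stack.mean(axis=0).ravel()
        long["sd"] = stack.std(axis=0, ddof=0).ravel()
        write_region_csv(out / f"N_sur_total_kg_ha_{scheme}.csv", long)
    nonagri_share = float(
        sum(r.surp_nonagri.values.sum() for r in results) /
        max(sum(r.surp_soil.values.sum() for r in results), 1e-300))
    cfg_json = json.dumps(config.__dict__, sort_keys=True, default=str)
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": config.__dict__,
        "members": [r.variant.label() for r in results],
        "member_ordering": "fertilizer slowest; manure source; manure "
                           "distribution; pasture scenario fastest",
        "non_agricultural_share_of_total_surplus": nonagri_share,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
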