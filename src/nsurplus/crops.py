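"""Crop-specific harvested areas and production, 1850-2019.

Non-fodder areas follow the cropland reconstruction: the year-2000 gridded
crop pattern is carried through time with the cropland dynamics of each
cell, then pinned to country x crop statistical totals (per-year ratios for
1961-2019, the 1961 ratio before).  Fodder-crop areas come from a
country-level source with gap-filling by neighbour proxy or an
Eastern-European aggregate ratio, and are back-cast before 1961 with the
fodder/cropland ratio of 1961.

Country crop production is back-cast before 1961 with the temporal
variability of wheat production, itself built from snapshot wheat yields
(linear interpolation between snapshot years, donor-mean yields for absent
countries).  Gridded production uses static year-2000 spatial weights
within each country, so country sums reproduce the input series exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import AnnualField, CountryCropYearTable, CountryYearTable
from .grid import GridSpec
from .landuse import YEAR0, harmonize_to_country
from .registry import FODDER_CROPS, NON_FODDER_CROPS, CountryRegistry

log = logging.getLogger(__name__)


@dataclass
class CropAreas:
    """Gridded harvested area (ha) per crop per year."""

    non_fodder: dict[str, AnnualField]
    fodder: dict[str, AnnualField]

    @property
    def all(self) -> dict[str, AnnualField]:
        return {**self.non_fodder, **self.fodder}


@dataclass
class CropProduction:
    """Gridded (kg per cell) and country-level (kg) production per crop."""

    gridded: dict[str, AnnualField]
    country: pd.DataFrame  # year-index, (country, crop) columns, kg


def _crop_dynamics(cropland: AnnualField, ref_year: int = 2000) -> np.ndarray:
    ref = cropland.at(ref_year)
    zero = ref == 0
    denom = np.where(zero, 1.0, ref)
    dyn = np.where(zero, 1.0, cropland.values / denom)
    return dyn


def reconstruct_nonfodder_areas(
    monfreda_2000: dict[str, np.ndarray],
    cropland: AnnualField,
    fao_crop_areas: CountryCropYearTable,
    grid: GridSpec,
    registry: CountryRegistry,
) -> dict[str, AnnualField]:
    """Year-2000 crop patterns x cropland dynamics, pinned to country tables."""
    dyn = _crop_dynamics(cropland)
    out: dict[str, AnnualField] = {}
    for crop in NON_FODDER_CROPS:
        pattern = np.asarray(monfreda_2000[crop], float)
        field = AnnualField(f"A_{crop}", "ha", cropland.year0,
                            np.maximum(pattern[None, :] * dyn, 0.0))
        cols = {u: fao_crop_areas.df[(u, crop)]
                for u in fao_crop_areas.countries if (u, crop) in fao_crop_areas.df.columns}
        table = CountryYearTable(pd.DataFrame(cols), units="ha")
        out[crop] = harmonize_to_country(field, table, grid, registry)
    total = sum(f.values for f in out.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        over = total > 2.0 * np.where(cropland.values > 0, cropland.values, np.inf)
    if over.any():
        log.warning("crop areas exceed 2x cropland in %d cell-years (multi-cropping?)",
                    int(over.sum()))
    return out


def _country_cropland(cropland: AnnualField, grid: GridSpec) -> pd.DataFrame:
    data = {int(u): cropland.values[:, grid.country_id == u].sum(axis=1)
            for u in grid.countries}
    return pd.DataFrame(data, index=pd.Index(cropland.years, name="year"))


def complete_fodder_country_series(
    einarsson_areas: CountryCropYearTable,
    cropland: AnnualField,
    grid: GridSpec,
    registry: CountryRegistry,
) -> pd.DataFrame:
    """Complete country x fodder-crop areas over the full 1850-2019 span.

    Gap rules for missing (country, year) entries in the source: borrow the
    fodder/cropland ratio from the mapped neighbour country where one is
    defined, otherwise use the pooled ratio of the Eastern-European donor
    countries in 1992; in both cases the ratio multiplies the missing
    country's own cropland area.  Years before 1961 use each country's 1961
    fodder/cropland ratio.
    """
    cl = _country_cropland(cropland, grid)
    years = cl.index
    donors = sorted(registry.east_eu_donors)
    out: dict[tuple[int, str], np.ndarray] = {}
    for u in grid.countries:
        u = int(u)
        for crop in FODDER_CROPS:
            series = np.full(len(years), np.nan)
            src = None
            if (u, crop) in einarsson_areas.df.columns:
                src = einarsson_areas.df[(u, crop)]
                for y, v in src.items():
                    if not np.isnan(v) and y in years:
                        series[years.get_loc(y)] = v
            # fill reported-era gaps with ratio-based rules
            missing = np.isnan(series) & (years >= 1961)
            if missing.any():
                if u in registry.proxy_map:
                    p = registry.proxy_map[u]
                    pseries = einarsson_areas.df.get((p, crop))
                    for t in np.flatnonzero(missing):
                        y = years[t]
                        pv = pseries.get(y, np.nan) if pseries is not None else np.nan
                        if not np.isnan(pv) and cl.at[y, p] > 0:
                            series[t] = pv / cl.at[y, p] * cl.at[y, u]
                missing = np.isnan(series) & (years >= 1961)
                if missing.any() and donors:
                    num = sum(einarsson_areas.df.get((d, crop), pd.Series(dtype=float)).get(1992, 0.0)
                              for d in donors)
                    den = sum(cl.at[1992, d] for d in donors)
                    ratio = num / den if den > 0 else 0.0
                    series[missing] = ratio * cl[u].to_numpy()[missing]
            # pre-1961 back-cast with the 1961 fodder/cropland ratio
            v1961 = series[years.get_loc(1961)]
            cl1961 = cl.at[1961, u]
            ratio = v1961 / cl1961 if cl1961 > 0 and not np.isnan(v1961) else 0.0
            pre = years < 1961
            series[pre] = ratio * cl[u].to_numpy()[pre]
            out[(u, crop)] = series
    df = pd.DataFrame(out, index=years)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["country", "crop"])
    return df


def downscale_country_series(
    country_series: pd.DataFrame,
    weights_2000: dict[str, np.ndarray],
    cropland: AnnualField,
    grid: GridSpec,
    *,
    dynamic: bool,
    units: str,
    prefix: str,
) -> dict[str, AnnualField]:
    """Distribute country x crop x year series onto the grid.

    With ``dynamic=True`` the year-2000 pattern is modulated by cropland
    dynamics before normalisation (used for areas); otherwise static weights
    are used (used for production).  Countries whose weights sum to zero but
    have a positive series fall back to a uniform split over the country's
    year-2000 cropland cells (or all cells if none).
    """
    dyn = _crop_dynamics(cropland) if dynamic else np.ones_like(cropland.values)
    years = country_series.index
    year0 = int(years[0])
    crops = sorted({c for _, c in country_series.columns})
    out: dict[str, AnnualField] = {}
    for crop in crops:
        values = np.zeros((len(years), grid.n_cells))
        base = np.asarray(weights_2000.get(crop, np.zeros(grid.n_cells)), float)
        for u in grid.countries:
            u = int(u)
            if (u, crop) not in country_series.columns:
                continue
            cells = grid.cells_of(u)
            series = country_series[(u, crop)].to_numpy()
            w = base[cells][None, :] * dyn[:, cells]
            wsum = w.sum(axis=1)
            fallback = wsum <= 0
            if fallback.any() and np.any(series[fallback] > 0):
                log.warning("downscale %s: country %d uniform fallback in %d years",
                            crop, u, int(fallback.sum()))
                crop_cells = cropland.at(2000)[cells] > 0
                uni = crop_cells / max(crop_cells.sum(), 1) if crop_cells.any() \
                    else np.full(len(cells), 1.0 / len(cells))
                w[fallback] = uni
                wsum = w.sum(axis=1)
            share = w / np.where(wsum > 0, wsum, 1.0)[:, None]
            values[:, cells] = series[:, None] * share
        out[crop] = AnnualField(f"{prefix}_{crop}", units, year0, values)
    return out


def interpolate_snapshot_yields(
    owd_yields: pd.DataFrame,
    year0: int = YEAR0,
    year1: int = 1960,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Annual wheat yields (kg/ha) from snapshot years, per country.

    Linear interpolation between snapshot years, clamped outside; countries
    absent from the source get the mean yield of the reporting countries.
    """
    years = np.arange(year0, year1 + 1)
    snap_years = owd_yields.index.to_numpy(dtype=int)
    cols = {}
    reporting = [u for u in owd_yields.columns if owd_yields[u].notna().all()]
    for u in owd_yields.columns:
        if u in reporting:
            cols[u] = np.interp(years, snap_years, owd_yields[u].to_numpy(float))
    donor_mean = np.mean([cols[u] for u in reporting], axis=0) if reporting else np.zeros(len(years))
    for u in owd_yields.columns:
        if u not in cols:
            cols[u] = donor_mean
    return pd.DataFrame(cols, index=pd.Index(years, name="year")), donor_mean


def backcast_wheat_production(
    owd_yields: pd.DataFrame,
    wheat_area_country: pd.DataFrame,
    countries: list[int],
) -> pd.DataFrame:
    """Country wheat production (kg) 1850-1960 = interpolated yield x area."""
    yields, donor_mean = interpolate_snapshot_yields(owd_yields)
    years = yields.index
    out = {}
    for u in countries:
        y = yields[u].to_numpy() if u in yields.columns else donor_mean
        area = wheat_area_country[u].loc[years].to_numpy()
        out[u] = y * area
    return pd.DataFrame(out, index=years)


def backcast_all_production(
    pro_1961: pd.Series,
    wheat_owd: pd.DataFrame,
    wheat_fao_1961: pd.Series,
) -> pd.DataFrame:
    """Scale every crop's 1961 production by the wheat production trajectory.

    ``pro_1961`` is indexed by (country, crop); returns a 1850-1960 frame
    with (country, crop) columns.  A zero wheat-1961 reference carries the
    1961 value unchanged (ratio 1) with a warning.
    """
    years = wheat_owd.index
    cols = {}
    for (u, crop), p61 in pro_1961.items():
        w61 = float(wheat_fao_1961.get(u, 0.0))
        if w61 == 0:
            if p61 > 0:
                log.warning("backcast: country %s zero wheat 1961; production held flat", u)
            ratio = np.ones(len(years))
        else:
            ratio = wheat_owd[u].to_numpy() / w61
        cols[(u, crop)] = ratio * float(p61)
    df = pd.DataFrame(cols, index=years)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["country", "crop"])
    return df


def build_country_production(
    fao_production: CountryCropYearTable,
    fodder_production: pd.DataFrame,
    owd_yields: pd.DataFrame,
    wheat_areas: dict[str, AnnualField] | AnnualField,
    grid: GridSpec,
) -> pd.DataFrame:
    """Country x crop production (kg) over the full 1850-2019 span.

    1961-2019 from the statistical tables (non-fodder) and the fodder
    source; 1850-1960 back-cast via wheat: wheat itself from snapshot
    yields x harvested area, the other crops by the wheat trajectory.
    """
    wheat_field = wheat_areas["wheat"] if isinstance(wheat_areas, dict) else wheat_areas
    wheat_area_country = _country_cropland(wheat_field, grid)
    recent = pd.concat([fao_production.df, fodder_production.loc[fodder_production.index >= 1961]],
                       axis=1).loc[lambda d: d.index >= 1961]
    # leading gaps (series starting in 1992) take the first reported value
    recent = recent.ffill().bfill().fillna(0.0)
    countries = sorted({u for u, _ in recent.columns})
    wheat_owd = backcast_wheat_production(owd_yields, wheat_area_country, countries)
    wheat_fao_1961 = pd.Series({u: recent.at[1961, (u, "wheat")]
                                for u in countries if (u, "wheat") in recent.columns})
    pro_1961 = recent.loc[1961]
    early = backcast_all_production(pro_1961, wheat_owd, wheat_fao_1961)
    # wheat before 1961 is the snapshot-yield reconstruction itself
    for u in countries:
        if (u, "wheat") in early.columns:
            early[(u, "wheat")] = wheat_owd[u]
    full = pd.concat([early, recent]).sort_index()
    full.index.name = "year"
    return full


def reconstruct_crops(
    grid: GridSpec,
    registry: CountryRegistry,
    cropland: AnnualField,
    monfreda_areas: dict[str, np.ndarray],
    monfreda_production: dict[str, np.ndarray],
    fao_crop_areas: CountryCropYearTable,
    fao_production: CountryCropYearTable,
    einarsson_fodder_areas: CountryCropYearTable,
    einarsson_fodder_production: CountryCropYearTable,
    owd_yields: pd.DataFrame,
) -> tuple[CropAreas, CropProduction]:
    """Full crop stage: harvested areas (non-fodder + fodder) and production."""
    non_fodder = reconstruct_nonfodder_areas(
        monfreda_areas, cropland, fao_crop_areas, grid, registry)
    fodder_country = complete_fodder_country_series(
        einarsson_fodder_areas, cropland, grid, registry)
    fodder = downscale_country_series(
        fodder_country, monfreda_areas, cropland, grid,
        dynamic=True, units="ha", prefix="A")
    areas = CropAreas(non_fodder=non_fodder, fodder=fodder)

    fodder_pro_country = complete_fodder_country_series(
        einarsson_fodder_production, cropland, grid, registry)
    country_pro = build_country_production(
        fao_production, fodder_pro_country, owd_yields, non_fodder["wheat"], grid)
    gridded_pro = downscale_country_series(
        country_pro, monfreda_production, cropland, grid,
        dynamic=False, units="kg_per_cell", prefix="Pro")
    return areas, CropProduction(gridded=gridded_pro, country=country_pro)
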