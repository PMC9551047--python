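"""Atmospheric N deposition downscaling/allocation and biological N fixation.

Deposition arrives as a coarse monthly field (kg per ha of grid area per
month); each fine cell takes its nearest coarse cell's value (nearest
neighbour in cell-centre distance), months are summed to years, and years
beyond the source record hold the last available annual field.  The annual
total is then allocated to land types in proportion to their area share of
the cell; the sea fraction's deposition is discarded.

Fixation is area-based for pasture, forest (temperate vs boreal by
country), semi-natural vegetation and the N-fixing crops, and
production-based for fodder crops, whose per-kg rates are derived from a
country-level fixation/production source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import CoefficientSet
from .fields import AnnualField
from .grid import GridSpec
from .landuse import LanduseResult
from .registry import CountryRegistry

log = logging.getLogger(__name__)


@dataclass
class DepositionResult:
    total: AnnualField  # kg per cell on land (sea fraction discarded)
    dep_cr: AnnualField
    dep_past: AnnualField
    dep_for: AnnualField
    dep_natveg: AnnualField
    dep_nonveg: AnnualField
    dep_urban: AnnualField


@dataclass
class BNFResult:
    bnf_cr: AnnualField      # crop-area fixers + fodder production term
    bnf_past: AnnualField
    bnf_for: AnnualField
    bnf_natveg: AnnualField
    fodder_rates: pd.DataFrame  # country x fodder crop, kg N per kg product


def nearest_coarse_index(fine_coords: np.ndarray, coarse_coords: np.ndarray) -> np.ndarray:
    """Index of the nearest coarse coordinate for every fine coordinate."""
    fine = np.asarray(fine_coords, float)[:, None]
    coarse = np.asarray(coarse_coords, float)[None, :]
    return np.abs(fine - coarse).argmin(axis=1)


def downscale_deposition(
    coarse_monthly: np.ndarray,
    coarse_lat: np.ndarray,
    coarse_lon: np.ndarray,
    source_year0: int,
    grid: GridSpec,
    year0: int,
    year1: int,
) -> AnnualField:
    """Annual deposition rate on the fine grid (kg per ha of grid area).

    ``coarse_monthly`` has shape (n_years, 12, n_coarse_lat, n_coarse_lon).
    Years after the source's last year hold its final annual field.
    """
    if coarse_monthly.ndim != 4 or coarse_monthly.shape[1] != 12:
        raise ValueError("coarse deposition must be (years, 12, lat, lon)")
    annual_coarse = coarse_monthly.sum(axis=1)
    ilat = nearest_coarse_index(grid.lat_centers, coarse_lat)
    ilon = nearest_coarse_index(grid.lon_centers, coarse_lon)
    fine = annual_coarse[:, ilat[:, None], ilon[None, :]].reshape(len(annual_coarse), -1)
    years = np.arange(year0, year1 + 1)
    idx = np.clip(years - source_year0, 0, len(annual_coarse) - 1)
    return AnnualField("DEP_total", "kg_per_ha_grid", year0, fine[idx])


def allocate_deposition(
    total_rate: AnnualField,
    landuse: LanduseResult,
    grid: GridSpec,
) -> DepositionResult:
    """Split total deposition by each land type's share of the cell area."""
    if total_rate.units != "kg_per_ha_grid":
        raise ValueError("deposition rate must be kg per ha of grid area")
    per_cell = total_rate.values * grid.cell_area  # kg over the whole cell
    parts = {}
    land_total = np.zeros_like(per_cell)
    for key, area in (
        ("dep_cr", landuse.cropland), ("dep_past", landuse.pasture),
        ("dep_for", landuse.forest), ("dep_natveg", landuse.natveg),
        ("dep_nonveg", landuse.nonveg), ("dep_urban", landuse.urban),
    ):
        v = per_cell * area.values / grid.cell_area[None, :]
        parts[key] = AnnualField(key.upper(), "kg_per_cell", total_rate.year0, v)
        land_total += v
    total = AnnualField("DEP_land", "kg_per_cell", total_rate.year0, land_total)
    return DepositionResult(total=total, **parts)


def derive_fodder_bnf_rates(
    fodder_bnf: pd.DataFrame,
    fodder_production: pd.DataFrame,
) -> pd.DataFrame:
    """kg N fixed per kg product, per (country, fodder crop).

    Pooled over the years both series report: sum of fixation over sum of
    production.  Zero production with zero fixation gives rate 0.
    """
    crops = sorted({c for _, c in fodder_bnf.columns})
    countries = sorted({u for u, _ in fodder_bnf.columns})
    out = pd.DataFrame(0.0, index=countries, columns=crops)
    for u in countries:
        for c in crops:
            if (u, c) not in fodder_bnf.columns or (u, c) not in fodder_production.columns:
                continue
            b = fodder_bnf[(u, c)]
            p = fodder_production[(u, c)]
            ok = b.notna() & p.notna()
            psum = float(p[ok].sum())
            bsum = float(b[ok].sum())
            if psum > 0:
                out.at[u, c] = bsum / psum
            elif bsum > 0:
                raise ValueError(f"country {u}, {c}: fixation without production")
    return out


def compute_bnf(
    landuse: LanduseResult,
    crop_areas: dict[str, AnnualField],
    fodder_production_gridded: dict[str, AnnualField],
    fodder_rates: pd.DataFrame,
    coefficients: CoefficientSet,
    registry: CountryRegistry,
    grid: GridSpec,
) -> BNFResult:
    """Area-based fixation for land types and fixing crops; per-product for fodder."""
    year0 = landuse.cropland.year0
    shape = landuse.cropland.values.shape
    bnf_cr = np.zeros(shape)
    for crop, rate in coefficients.bnf_crop_rate.items():
        if crop in crop_areas:
            bnf_cr += rate * crop_areas[crop].values
    for crop, field in fodder_production_gridded.items():
        rate_cell = np.zeros(grid.n_cells)
        for u in grid.countries:
            rate_cell[grid.country_id == u] = float(fodder_rates.at[int(u), crop]) \
                if int(u) in fodder_rates.index and crop in fodder_rates.columns else 0.0
        bnf_cr += rate_cell[None, :] * field.values
    bnf_past = coefficients.bnf_pasture * landuse.pasture.values
    forest_rate = np.full(grid.n_cells, coefficients.bnf_forest_temperate)
    for u in registry.boreal:
        forest_rate[grid.country_id == u] = coefficients.bnf_forest_boreal
    bnf_for = forest_rate[None, :] * landuse.forest.values
    bnf_natveg = coefficients.bnf_natveg * landuse.natveg.values
    return BNFResult(
        bnf_cr=AnnualField("BNF_cr", "kg_per_cell", year0, bnf_cr),
        bnf_past=AnnualField("BNF_past", "kg_per_cell", year0, bnf_past),
        bnf_for=AnnualField("BNF_For", "kg_per_cell", year0, bnf_for),
        bnf_natveg=AnnualField("BNF_NatVeg", "kg_per_cell", year0, bnf_natveg),
        fodder_rates=fodder_rates)
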