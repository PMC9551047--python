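"""Annual gridded land-use reconstruction, 1850-2019.

The reconstruction carries a year-2000 spatial snapshot of cropland and
pasture through time with cell-level temporal ratios from a decadal/annual
land-use history, pins country totals to the statistical (FAOSTAT-style)
tables for 1961-2019, enforces physical consistency (agricultural area may
not exceed the cell area, excess redistributed within the country without
changing country totals), and splits the residual non-agricultural area
into forest, semi-natural vegetation, non-vegetated and urban shares using
static year-2000 land-cover proportions.

Degenerate-denominator conventions: a temporal or harmonization ratio with
zero denominator is taken as 1 (the value is carried unchanged) and logged;
a cell whose non-agricultural land-cover fractions sum to zero assigns the
whole residual to semi-natural vegetation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fields import AnnualField, CountryYearTable
from .grid import GridSpec
from .redistribute import CapacityError, redistribute_equal_spare
from .registry import CountryRegistry

log = logging.getLogger(__name__)

YEAR0, YEAR1 = 1850, 2019


@dataclass
class LanduseResult:
    """Harmonized land-use areas (ha), all on the same grid and year range."""

    cropland: AnnualField       # C_A_cr
    pasture: AnnualField        # C_A_past
    agricultural: AnnualField   # C_A_agri = cropland + pasture
    non_agricultural: AnnualField
    forest: AnnualField
    natveg: AnnualField
    nonveg: AnnualField
    urban: AnnualField


def interpolate_decadal(
    knot_years: np.ndarray,
    knot_values: np.ndarray,
    annual_years: np.ndarray,
    annual_values: np.ndarray,
    year0: int = YEAR0,
    year1: int = YEAR1,
) -> np.ndarray:
    """Annual series from decadal knots plus a recent annual segment.

    Linear interpolation between consecutive decadal knots; the annual
    segment overrides where it is defined; years beyond the last annual
    year are clamped to its value.  Returns shape (year1-year0+1, n_cells).
    """
    knot_years = np.asarray(knot_years, int)
    annual_years = np.asarray(annual_years, int)
    if np.any(np.diff(knot_years) <= 0) or np.any(np.diff(annual_years) <= 0):
        raise ValueError("year knots must be strictly increasing")
    knot_values = np.atleast_2d(np.asarray(knot_values, float))
    annual_values = np.atleast_2d(np.asarray(annual_values, float))
    years = np.arange(year0, year1 + 1)
    n_cells = knot_values.shape[1] if knot_values.ndim == 2 else 1
    out = np.empty((len(years), n_cells))
    for j in range(n_cells):
        out[:, j] = np.interp(years, knot_years, knot_values[:, j])
    # annual segment wins where defined; later years clamp to its last value
    for t, y in enumerate(years):
        if y >= annual_years[0]:
            k = min(np.searchsorted(annual_years, y), len(annual_years) - 1)
            if annual_years[k] > y and k > 0:
                k -= 1
            out[t] = annual_values[k]
    return out


def temporal_ratio(series: AnnualField, ref_year: int = 2000) -> AnnualField:
    """R(y) = A(y) / A(ref_year) per cell; zero reference gives R = 1."""
    ref = series.at(ref_year)
    zero = ref == 0
    if zero.any():
        log.warning("temporal_ratio: %d cells with zero %d reference; ratio set to 1",
                    int(zero.sum()), ref_year)
    denom = np.where(zero, 1.0, ref)
    ratio = np.where(zero, 1.0, series.values / denom)
    return AnnualField(f"R_{series.name}", "dimensionless", series.year0, ratio)


def apply_snapshot(snapshot_2000: np.ndarray, ratio: AnnualField, name: str) -> AnnualField:
    """Back-cast a year-2000 snapshot (ha per cell) with a temporal ratio."""
    values = np.maximum(ratio.values * np.asarray(snapshot_2000, float), 0.0)
    return AnnualField(name, "ha", ratio.year0, values)


def _merged_members(registry: CountryRegistry, country: int, year: int) -> tuple[int, ...]:
    g = registry.merge_group_of(country)
    if g is not None and year < g.split_year:
        return g.members
    return (country,)


def harmonize_to_country(
    field: AnnualField,
    table: CountryYearTable,
    grid: GridSpec,
    registry: CountryRegistry,
) -> AnnualField:
    """Scale each country's cells so sums match the country table.

    1961-2019 use the per-year ratio; 1850-1960 reuse the 1961 ratio.
    Countries flagged as unreported before 1992 use the 1992 ratio for all
    years before 1992.  Merged reporting groups share a single ratio over
    their combined footprint while merged (the combined value is stored
    under the first member's column).
    """
    values = field.values.copy()
    years = field.years
    table_years = set(int(y) for y in table.years)

    def _ratio(country: int, year: int) -> float:
        members = _merged_members(registry, country, year)
        col = members[0]
        target = table.df.at[year, col] if year in table_years and col in table.df.columns else np.nan
        if np.isnan(target):
            return np.nan
        cells = np.concatenate([grid.cells_of(m) for m in members])
        current = field.values[field.index_of(year), cells].sum()
        if current == 0:
            if target > 0:
                raise ValueError(
                    f"country {country}, year {year}: table demands {target:.6g} ha "
                    "but no gridded area to scale")
            log.warning("harmonize: country %d year %d zero/zero; ratio 1", country, year)
            return 1.0
        return float(target) / float(current)

    for country in grid.countries:
        cells = grid.cells_of(country)
        anchor_year = 1992 if country in registry.missing_before_1992 else 1961
        anchor = _ratio(country, anchor_year)
        if np.isnan(anchor):
            raise ValueError(f"country {country}: no table value at anchor year {anchor_year}")
        for t, y in enumerate(years):
            if y < anchor_year:
                r = anchor
            else:
                r = _ratio(country, int(y))
                if np.isnan(r):
                    r = anchor
            values[t, cells] *= r
    return AnnualField(f"C_{field.name}", "ha", field.year0, values)


def enforce_physical_consistency(
    cropland: AnnualField,
    pasture: AnnualField,
    grid: GridSpec,
) -> tuple[AnnualField, AnnualField]:
    """Cap cropland+pasture at the physical cell area, conserving country totals.

    Excess agricultural area in a cell is removed pro-rata from cropland and
    pasture and redistributed equally over the country's cells with spare
    capacity, carrying the donor composition so both components' country
    totals are conserved exactly.
    """
    cr = cropland.values.copy()
    pa = pasture.values.copy()
    for t in range(cropland.n_years):
        agri = cr[t] + pa[t]
        if not np.any(agri > grid.cell_area * (1 + 1e-12)):
            continue
        for country in grid.countries:
            cells = grid.cells_of(country)
            if not np.any(agri[cells] > grid.cell_area[cells]):
                continue
            try:
                _, (c_cr, c_pa) = redistribute_equal_spare(
                    agri[cells], grid.cell_area[cells],
                    companions=(cr[t, cells], pa[t, cells]))
            except CapacityError as e:
                raise CapacityError(
                    f"country {country}, year {cropland.year0 + t}: {e}") from e
            cr[t, cells] = c_cr
            pa[t, cells] = c_pa
    return (AnnualField(cropland.name, "ha", cropland.year0, cr),
            AnnualField(pasture.name, "ha", pasture.year0, pa))


def decompose_nonagricultural(
    non_agri: AnnualField,
    glc_fractions: dict[str, np.ndarray],
) -> dict[str, AnnualField]:
    """Split the residual area by static year-2000 land-cover proportions.

    ``glc_fractions`` maps 'forest', 'natveg', 'nonveg', 'urban' to per-cell
    cover fractions; they are renormalised by their sum.  Cells whose four
    fractions sum to zero assign the whole residual to semi-natural
    vegetation.
    """
    keys = ("forest", "natveg", "nonveg", "urban")
    raw = np.stack([np.asarray(glc_fractions[k], float) for k in keys])
    total = raw.sum(axis=0)
    zero = total == 0
    if zero.any():
        log.warning("decompose: %d cells with zero land-cover fractions; "
                    "residual assigned to semi-natural vegetation", int(zero.sum()))
    rel = np.where(zero, 0.0, raw / np.where(zero, 1.0, total))
    rel[1, zero] = 1.0  # natveg catches the degenerate cells
    out = {}
    for k, r in zip(keys, rel):
        out[k] = AnnualField(f"A_{k}", "ha", non_agri.year0, non_agri.values * r)
    return out


def reconstruct_landuse(
    grid: GridSpec,
    registry: CountryRegistry,
    snapshot_cropland: np.ndarray,
    snapshot_pasture: np.ndarray,
    hyde_cropland: AnnualField,
    hyde_pasture: AnnualField,
    fao_cropland: CountryYearTable,
    fao_pasture: CountryYearTable,
    glc_fractions: dict[str, np.ndarray],
) -> LanduseResult:
    """Full land-use stage: back-cast, harmonize, correct, decompose."""
    a_cr = apply_snapshot(snapshot_cropland, temporal_ratio(hyde_cropland), "A_cr")
    a_past = apply_snapshot(snapshot_pasture, temporal_ratio(hyde_pasture), "A_past")
    c_cr = harmonize_to_country(a_cr, fao_cropland, grid, registry)
    c_past = harmonize_to_country(a_past, fao_pasture, grid, registry)
    c_cr, c_past = enforce_physical_consistency(c_cr, c_past, grid)
    agri = AnnualField("C_A_agri", "ha", c_cr.year0, c_cr.values + c_past.values)
    non_agri = AnnualField("A_NonAgri", "ha", c_cr.year0,
                           np.maximum(grid.cell_area[None, :] - agri.values, 0.0))
    parts = decompose_nonagricultural(non_agri, glc_fractions)
    return LanduseResult(
        cropland=c_cr, pasture=c_past, agricultural=agri, non_agricultural=non_agri,
        forest=parts["forest"], natveg=parts["natveg"],
        nonveg=parts["nonveg"], urban=parts["urban"])
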