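"""Animal manure: country ratios, gridding, cap, cropland/pasture split.

Country totals of manure applied to soil and left on pasture (from either
of two statistical sources) are turned into per-cell amounts by scaling a
gridded manure-production field with country-year ratios; years outside
the production record are padded with the nearest available year, and the
pre-statistical era reuses the 1961 ratios.  Application in any cell is
capped at a maximum rate per hectare of agricultural area (applied + left
jointly); the excess flows to neighbouring agricultural cells of the same
country through expanding rings, conserving country totals.  The capped
amount applied to soil is finally split between cropland and pasture,
either uniformly by area or according to external country shares; manure
on pasture additionally includes the amount left by grazing animals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .fields import AnnualField, CountryYearTable
from .grid import GridSpec
from .redistribute import CapacityError, redistribute_rings

log = logging.getLogger(__name__)


class ManureSource(str, Enum):
    FAOSTAT = "FAOSTAT"
    EINARSSON = "EINARSSON"


class ManureDistribution(str, Enum):
    UNIFORM = "UNIFORM"
    SHARES = "SHARES"


@dataclass
class ManureResult:
    source: ManureSource
    distribution: ManureDistribution
    man_cr: AnnualField    # kg per cell: applied to cropland
    man_past: AnnualField  # kg per cell: applied to pasture + left on pasture


def pad_production(production: AnnualField, year0: int, year1: int) -> AnnualField:
    """Extend a gridded production field to [year0, year1] by edge padding."""
    years = np.arange(year0, year1 + 1)
    idx = np.clip(years - production.year0, 0, production.n_years - 1)
    return AnnualField(production.name, production.units, year0, production.values[idx])


def compute_country_ratios(
    country_applied: CountryYearTable,
    country_left: CountryYearTable,
    production: AnnualField,
    grid: GridSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per country-year ratios of applied / left amounts to production.

    Production must be in kg per cell.  Ratios cover 1850-2019: statistical
    years use their own ratio, earlier years the 1961 ratio; gaps inside
    the record carry the nearest earlier ratio.
    """
    if production.units != "kg_per_cell":
        raise ValueError("production must be kg_per_cell (convert first)")
    years = production.years
    r_app = pd.DataFrame(index=pd.Index(years, name="year"),
                         columns=country_applied.df.columns, dtype=float)
    r_left = r_app.copy()
    for u in country_applied.df.columns:
        prod = production.country_sum(grid, int(u))
        prod_s = pd.Series(prod, index=years)
        for table, out in ((country_applied, r_app), (country_left, r_left)):
            stat = table.df[u]
            r = pd.Series(np.nan, index=years)
            for y in stat.index:
                v = stat.loc[y]
                if np.isnan(v) or y not in r.index:
                    continue
                p = prod_s.loc[y]
                if p == 0:
                    if v > 0:
                        raise ValueError(
                            f"country {u}, year {y}: manure amount {v:.4g} with "
                            "zero gridded production")
                    r.loc[y] = 0.0
                else:
                    r.loc[y] = v / p
            r = r.ffill()            # gaps inside the record
            r.loc[:1960] = r.loc[1961]  # pre-statistical era: 1961 ratio
            out[u] = r.bfill().to_numpy()
    return r_app, r_left


def grid_manure(
    ratios: pd.DataFrame,
    production: AnnualField,
    grid: GridSpec,
) -> AnnualField:
    """Cell amount = country ratio x cell production (kg per cell)."""
    values = np.zeros_like(production.values)
    years = production.years
    for u in ratios.columns:
        cells = grid.cells_of(int(u))
        r = ratios[u].reindex(years).to_numpy(dtype=float)
        values[:, cells] = r[:, None] * production.values[:, cells]
    return AnnualField("Man", "kg_per_cell", production.year0, values)


def cap_and_redistribute(
    applied: AnnualField,
    left: AnnualField,
    agricultural: AnnualField,
    grid: GridSpec,
    cap: float,
) -> tuple[AnnualField, AnnualField]:
    """Cap applied+left at ``cap`` kg per agricultural ha, per cell.

    Excess moves to neighbouring agricultural cells of the same country in
    expanding rings, removed pro-rata from the applied and left components
    and deposited at the pooled composition, so each component's country
    total is conserved.  A country-year whose total manure exceeds its
    total capacity is reported as an error.
    """
    if not 170.0 <= cap <= 250.0:
        raise ValueError("cap must lie in [170, 250] kg per agricultural ha")
    app = applied.values.copy()
    lef = left.values.copy()
    for t in range(applied.n_years):
        capacity = cap * agricultural.values[t]
        total = app[t] + lef[t]
        if not np.any(total > capacity * (1 + 1e-12) + 1e-12):
            continue
        for u in grid.countries:
            member = grid.country_id == u
            if not np.any(total[member] > capacity[member] + 1e-12):
                continue
            try:
                _, (a, l) = redistribute_rings(
                    total * member, capacity, grid, member,
                    companions=(app[t] * member, lef[t] * member))
            except CapacityError as e:
                raise CapacityError(
                    f"country {int(u)}, year {applied.year0 + t}: {e}") from e
            app[t][member] = a[member]
            lef[t][member] = l[member]
    return (applied.like(app, name="Man_app_soil"), left.like(lef, name="Man_left_past"))


def _waterfill(base: np.ndarray, ceiling: np.ndarray, target: float) -> np.ndarray:
    """Scale ``base`` towards ``target`` total without exceeding ``ceiling``.

    Returns min(beta * base, ceiling) with beta chosen so the sum equals
    ``target`` (water-filling); falls back to ceiling-proportional weights
    when base is all zero.  Requires 0 <= target <= ceiling.sum().
    """
    base = np.asarray(base, float)
    ceiling = np.asarray(ceiling, float)
    if target <= 0:
        return np.zeros_like(base)
    if base.sum() <= 0:
        return target * ceiling / ceiling.sum()
    lo, hi = 0.0, 1.0
    while np.minimum(hi * base, ceiling).sum() < target and hi < 1e12:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * base, ceiling).sum() < target:
            lo = mid
        else:
            hi = mid
    out = np.minimum(hi * base, ceiling)
    s = out.sum()
    if s > 0:  # polish away bisection residue on unclipped cells
        free = out < ceiling - 1e-15
        deficit = target - s
        if np.any(free) and abs(deficit) > 0:
            out[free] += deficit * out[free] / max(out[free].sum(), 1e-300)
    return np.clip(out, 0.0, ceiling)


def distribute_to_cropland_pasture(
    applied: AnnualField,
    left: AnnualField,
    cropland: AnnualField,
    pasture: AnnualField,
    grid: GridSpec,
    source: ManureSource,
    distribution: ManureDistribution,
    cropland_share: pd.DataFrame | None = None,
) -> ManureResult:
    """Split applied manure between cropland and pasture; add left-on-pasture.

    UNIFORM assumes one application rate per cell across cropland and
    pasture, i.e. the cell's applied amount splits pro-rata to the two
    areas (a cell with equal areas splits 50/50).  SHARES rescales the
    country-year cropland fraction of applied manure to an external share,
    keeping the country total of applied manure unchanged.
    """
    agri = cropland.values + pasture.values
    with np.errstate(invalid="ignore", divide="ignore"):
        w_cr = np.where(agri > 0, cropland.values / np.where(agri > 0, agri, 1.0), 0.0)
    cr = applied.values * w_cr
    if distribution is ManureDistribution.SHARES:
        if cropland_share is None:
            raise ValueError("share-based distribution needs a cropland share table")
        years = applied.years
        for u in grid.countries:
            u = int(u)
            cells = grid.cells_of(u)
            tot = applied.values[:, cells].sum(axis=1)
            # years before the share record carry its first value (1961 share)
            share = cropland_share[u].reindex(years).ffill().bfill().to_numpy(dtype=float)
            for t in range(len(years)):
                if tot[t] <= 0:
                    continue
                cr[t, cells] = _waterfill(cr[t, cells], applied.values[t, cells],
                                          share[t] * tot[t])
    app_past = applied.values - cr
    man_past = app_past + left.values
    return ManureResult(
        source, distribution,
        AnnualField("Man_cr", "kg_per_cell", applied.year0, cr),
        AnnualField("Man_past", "kg_per_cell", applied.year0, man_past))
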