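"""Mineral fertilizer: country series, application rates, gridding, partition.

The country fertilizer series (kg N per country-year, 1850-2019) splices
the statistical era (1961-2019) onto a global production trend: nothing
before 1920, a linear bridge 1920-1924, the global trend 1925-1960 anchored
so its 1960 value meets the country's 1961 statistic.  Countries missing
before 1992 are filled with the temporal dynamics of the Eastern-European
donor pool; merged reporting pairs are split with the combined series'
dynamics anchored at the split year.

Application rates per crop come from industry (IFA-style) crop-group
amounts for 2014/15 divided by harvested areas; fodder crops and pasture
take the grassland rate; countries outside the source take the pooled
member (EU-28-like) rates.  Gridded amounts are adjusted by a single
country-year factor so aggregates match the country series exactly, and
the cropland/pasture split is produced in two variants: the rate-based
split itself, and a rescaling to externally given cropland/pasture shares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .fields import AnnualField, CountryYearTable
from .grid import GridSpec
from .landuse import YEAR0, YEAR1
from .registry import IFA_GROUP_TO_CROPS, NON_FODDER_CROPS, CountryRegistry, ifa_group_of

log = logging.getLogger(__name__)


class FertilizerApproach(str, Enum):
    IFA = "IFA"
    EINARSSON_SHARES = "EINARSSON_SHARES"


@dataclass
class FertilizerRates:
    """kg N per ha of harvested (crop) / grassland area per year, 2014/15."""

    crop_rate: pd.DataFrame   # country x crop
    grass_rate: pd.Series     # per country


@dataclass
class FertilizerResult:
    approach: FertilizerApproach
    fer_cr: AnnualField    # kg per cell
    fer_past: AnnualField  # kg per cell


def complete_country_fertilizer(
    fao_fert: CountryYearTable,
    holland_global: pd.Series,
    registry: CountryRegistry,
) -> CountryYearTable:
    """Country fertilizer applied to soil (kg), completed over 1850-2019."""
    years = np.arange(YEAR0, YEAR1 + 1)
    df = pd.DataFrame(index=pd.Index(years, name="year"),
                      columns=fao_fert.df.columns, dtype=float)
    stat = fao_fert.df.reindex(np.arange(1961, YEAR1 + 1))
    # Eastern-European donor pool dynamics for series missing before 1992
    donors = sorted(registry.east_eu_donors)
    donor_total = stat[[d for d in donors if d in stat.columns]].sum(axis=1) if donors else None
    for u in stat.columns:
        s = stat[u].copy()
        group = registry.merge_group_of(u)
        if group is not None:
            # merged era stored under the first member's column: split the
            # combined series by the members' shares at the split year
            lead = group.members[0]
            merged_years = s.index[s.index < group.split_year]
            combined = stat[lead].loc[merged_years]
            split_vals = stat.loc[group.split_year, list(group.members)]
            denom = float(split_vals.sum())
            share = float(stat.loc[group.split_year, u]) / denom if denom > 0 else 1.0 / len(group.members)
            s.loc[merged_years] = (combined * share).to_numpy()
        if u in registry.missing_before_1992 and s.loc[:1991].isna().any():
            if donor_total is None or donor_total.loc[1992] == 0:
                raise ValueError("Eastern-European donor pool missing: cannot fill "
                                 f"country {u} before 1992")
            fill_years = s.index[(s.index <= 1991) & s.isna()]
            s.loc[fill_years] = (donor_total.loc[fill_years] / donor_total.loc[1992]
                                 * s.loc[1992]).to_numpy()
        s = s.ffill().bfill()
        df.loc[1961:, u] = s.to_numpy()
    # pre-1961 global trend: zero through 1920, linear bridge, then anchored trend
    trend = pd.Series(0.0, index=pd.Index(np.arange(YEAR0, 1961), name="year"))
    h = holland_global.sort_index()
    h_last = float(h.loc[h.index.max()])
    if h_last <= 0:
        raise ValueError("global fertilizer production trend must end positive")
    for y in trend.index:
        if y <= 1920:
            trend.loc[y] = 0.0
        elif y < int(h.index.min()):
            # linear from zero at 1920 to the first trend value
            y1 = int(h.index.min())
            trend.loc[y] = (y - 1920) / (y1 - 1920) * (h.loc[y1] / h_last)
        elif y <= int(h.index.max()):
            trend.loc[y] = float(h.loc[y]) / h_last
    for u in df.columns:
        df.loc[:1960, u] = (trend * df.at[1961, u]).to_numpy()
    return CountryYearTable(df, units="kg")


def derive_ifa_rates(
    ifa_amounts: pd.DataFrame,
    fao_areas_2015: pd.DataFrame,
    grass_area_2015: pd.Series,
    registry: CountryRegistry,
) -> FertilizerRates:
    """Application rates for 2014/15 from crop-group amounts and areas.

    ``ifa_amounts``: member-country rows x columns = 13 crop groups plus
    'grassland' (kg).  ``fao_areas_2015``: country x crop harvested area
    (ha); ``grass_area_2015``: grassland area (temporary grassland plus
    pasture) per country (ha).  Non-member countries take the pooled rates
    of the members.
    """
    members = [u for u in ifa_amounts.index if u in registry.ifa_members]
    countries = sorted(set(fao_areas_2015.index) | set(registry.ids))

    def group_area(u: int, group: str) -> float:
        crops = IFA_GROUP_TO_CROPS[group]
        return float(sum(fao_areas_2015.at[u, c] for c in crops
                         if c in fao_areas_2015.columns)) if u in fao_areas_2015.index else 0.0

    pooled_rate: dict[str, float] = {}
    for group in list(IFA_GROUP_TO_CROPS) + ["grassland"]:
        amount = float(sum(ifa_amounts.at[u, group] for u in members
                           if group in ifa_amounts.columns))
        if group == "grassland":
            area = float(sum(grass_area_2015.get(u, 0.0) for u in members))
        else:
            area = float(sum(group_area(u, group) for u in members))
        pooled_rate[group] = amount / area if area > 0 else 0.0

    crop_rate = pd.DataFrame(0.0, index=countries, columns=list(NON_FODDER_CROPS))
    grass_rate = pd.Series(0.0, index=countries)
    for u in countries:
        is_member = u in members
        for crop in NON_FODDER_CROPS:
            group = ifa_group_of(crop)
            if is_member:
                amount = float(ifa_amounts.at[u, group]) if group in ifa_amounts.columns else 0.0
                area = group_area(u, group)
                if area == 0:
                    if amount > 0:
                        raise ValueError(
                            f"country {u}, group {group}: positive fertilizer amount "
                            "with zero harvested area")
                    rate = 0.0
                else:
                    rate = amount / area
            else:
                rate = pooled_rate[group]
            crop_rate.at[u, crop] = rate
        if is_member:
            ga = float(grass_area_2015.get(u, 0.0))
            amount = float(ifa_amounts.at[u, "grassland"])
            if ga == 0 and amount > 0:
                raise ValueError(f"country {u}: grassland amount with zero area")
            grass_rate.at[u] = amount / ga if ga > 0 else 0.0
        else:
            grass_rate.at[u] = pooled_rate["grassland"]
    return FertilizerRates(crop_rate=crop_rate, grass_rate=grass_rate)


def _per_cell(series: pd.Series, grid: GridSpec) -> np.ndarray:
    out = np.zeros(grid.n_cells)
    for u in grid.countries:
        out[grid.country_id == u] = float(series.get(int(u), 0.0))
    return out


def grid_unadjusted(
    rates: FertilizerRates,
    crop_areas: dict[str, AnnualField],
    fodder_areas: dict[str, AnnualField],
    pasture: AnnualField,
    grid: GridSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Unadjusted gridded fertilizer on cropland and pasture (kg per cell)."""
    grass_cell = _per_cell(rates.grass_rate, grid)
    cr = np.zeros_like(pasture.values)
    for crop, field in crop_areas.items():
        cr += _per_cell(rates.crop_rate[crop], grid)[None, :] * field.values
    for field in fodder_areas.values():
        cr += grass_cell[None, :] * field.values
    past = grass_cell[None, :] * pasture.values
    return cr, past


def grid_and_adjust(
    rates: FertilizerRates,
    crop_areas: dict[str, AnnualField],
    fodder_areas: dict[str, AnnualField],
    pasture: AnnualField,
    agricultural: AnnualField,
    nfer_soil: CountryYearTable,
    grid: GridSpec,
) -> tuple[AnnualField, AnnualField]:
    """Scale the rate-based pattern so country sums equal the country series.

    One scalar per country-year preserves the relative rate structure
    across crops.  A country-year with a positive target but an all-zero
    unadjusted pattern falls back to a uniform split over agricultural
    area, split between cropland and pasture pro-rata to their areas.
    """
    cr, past = grid_unadjusted(rates, crop_areas, fodder_areas, pasture, grid)
    years = pasture.years
    cropland_vals = agricultural.values - pasture.values
    for u in grid.countries:
        cells = grid.cells_of(int(u))
        target = nfer_soil.df[int(u)].reindex(years).to_numpy(dtype=float)
        unadj = cr[:, cells].sum(axis=1) + past[:, cells].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(unadj > 0, target / np.where(unadj > 0, unadj, 1.0), 0.0)
        cr[:, cells] *= f[:, None]
        past[:, cells] *= f[:, None]
        fallback = (unadj <= 0) & (target > 0)
        if fallback.any():
            log.warning("fertilizer: country %d uniform fallback in %d years",
                        int(u), int(fallback.sum()))
            agri = agricultural.values[:, cells]
            agri_sum = agri.sum(axis=1)
            for t in np.flatnonzero(fallback):
                if agri_sum[t] <= 0:
                    raise ValueError(f"country {u}: fertilizer demanded on zero "
                                     f"agricultural area in year {years[t]}")
                amount = target[t] * agri[t] / agri_sum[t]
                with np.errstate(invalid="ignore", divide="ignore"):
                    w_cr = np.where(agri[t] > 0, cropland_vals[t, cells] / agri[t], 0.0)
                cr[t, cells] += amount * w_cr
                past[t, cells] += amount * (1 - w_cr) * (agri[t] > 0)
    return (AnnualField("N_fer_cr", "kg_per_cell", int(years[0]), cr),
            AnnualField("N_fer_past", "kg_per_cell", int(years[0]), past))


def fill_country_shares(
    shares: pd.DataFrame,
    registry: CountryRegistry,
    countries: list[int],
) -> pd.DataFrame:
    """Complete a country x year cropland-share table (values in [0, 1]).

    Gaps borrow the mapped neighbour's share where defined, otherwise the
    mean share of the Eastern-European donor countries; a country entirely
    absent defaults to the all-country mean.
    """
    years = shares.index
    donors = [d for d in sorted(registry.east_eu_donors) if d in shares.columns]
    donor_mean = shares[donors].mean(axis=1) if donors else shares.mean(axis=1)
    overall = shares.mean(axis=1)
    out = {}
    for u in countries:
        s = shares[u].copy() if u in shares.columns else pd.Series(np.nan, index=years)
        if s.isna().any():
            p = registry.proxy_map.get(u)
            if p is not None and p in shares.columns:
                s = s.fillna(shares[p])
            s = s.fillna(donor_mean).fillna(overall).fillna(0.5)
        out[u] = s
    return pd.DataFrame(out, index=years).clip(0.0, 1.0)


def partition_fertilizer(
    fer_cr: AnnualField,
    fer_past: AnnualField,
    approach: FertilizerApproach,
    grid: GridSpec,
    cropland: AnnualField,
    pasture: AnnualField,
    cropland_share: pd.DataFrame | None = None,
) -> FertilizerResult:
    """Final cropland/pasture split for one approach.

    The rate-based approach returns the adjusted gridded amounts as they
    are.  The share-based approach rescales, per country-year, the cropland
    and pasture totals to the externally given cropland share of the (same)
    country total, preserving within-country spatial patterns.
    """
    if approach is FertilizerApproach.IFA:
        return FertilizerResult(approach, fer_cr, fer_past)
    if cropland_share is None:
        raise ValueError("share-based partitioning needs a cropland share table")
    cr = fer_cr.values.copy()
    past = fer_past.values.copy()
    years = fer_cr.years
    for u in grid.countries:
        u = int(u)
        cells = grid.cells_of(u)
        tot_cr = cr[:, cells].sum(axis=1)
        tot_past = past[:, cells].sum(axis=1)
        total = tot_cr + tot_past
        # years before the share record carry its first value (1961 share)
        share = cropland_share[u].reindex(years).ffill().bfill().to_numpy(dtype=float)
        target_cr = share * total
        target_past = (1 - share) * total
        for t in range(len(years)):
            if total[t] <= 0:
                continue
            if tot_cr[t] > 0:
                cr[t, cells] *= target_cr[t] / tot_cr[t]
            elif target_cr[t] > 0:
                w = cropland.values[t, cells]
                if w.sum() <= 0:
                    w = np.ones(len(cells))
                cr[t, cells] = target_cr[t] * w / w.sum()
            if tot_past[t] > 0:
                past[t, cells] *= target_past[t] / tot_past[t]
            elif target_past[t] > 0:
                w = pasture.values[t, cells]
                if w.sum() <= 0:
                    w = np.ones(len(cells))
                past[t, cells] = target_past[t] * w / w.sum()
    return FertilizerResult(
        approach,
        fer_cr.like(cr, name="N_fer_cr"),
        fer_past.like(past, name="N_fer_past"))
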