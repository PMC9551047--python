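"""Synthetic input bundles emulating the pipeline's external databases.

The generator produces, from a single seed, a complete input bundle with
the statistical structure of the real sources: a year-2000 land-use
snapshot, a decadal+annual land-use history, country statistical tables
for 1961-2019 with realistic gap patterns (series missing before 1992,
merged country reporting), crop-group fertilizer amounts for 2014/15, a
gridded manure-production history, coarse monthly deposition, a global
fertilizer-production trend for the pre-statistical era, and snapshot
wheat yields.  Spatial fields are low-pass-filtered Gaussian noise
squashed into valid ranges, which gives plausible spatial autocorrelation
without any external data.

In *truth mode* the bundle is generated by exactly inverting the
pipeline's deterministic maps from a chosen gridded truth (country tables
are aggregates of the truth, snapshots are its year-2000 slice, gap
patterns are disabled, caps never bind), so running the pipeline on the
bundle must reproduce the truth fields.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .fields import AnnualField, CountryCropYearTable, CountryYearTable
from .grid import GridSpec
from .registry import ALL_CROPS, FODDER_CROPS, IFA_GROUPS, NON_FODDER_CROPS, CountryRegistry

YEAR0, YEAR1 = 1850, 2019


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_lat: int = 20
    n_lon: int = 20
    resolution: float = 0.5
    lat_north: float = 60.0
    lon_west: float = 0.0
    n_countries: int = 8
    year0: int = YEAR0
    year1: int = YEAR1
    #: peak fraction of a cell occupied by cropland / pasture
    cropland_intensity: float = 0.35
    pasture_intensity: float = 0.25
    #: peak country-mean fertilizer application, kg N per agricultural ha
    fertilizer_scale: float = 60.0
    #: manure production scale, kg N per ha of grid area
    manure_scale: float = 25.0
    #: deposition scale, kg N per ha per yr
    deposition_scale: float = 8.0
    deposition_coarse_factor: int = 4
    gap_missing_before_1992: bool = True
    gap_merged_countries: bool = True
    truth_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ValueError("need n_countries >= 3 to exercise gap rules")
        if self.n_lat % self.deposition_coarse_factor or self.n_lon % self.deposition_coarse_factor:
            raise ValueError("grid size must be a multiple of the deposition coarse factor")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component generator derived from the master seed."""
        sub = zlib.crc32(component.encode()) & 0x7FFFFFFF
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, sub])

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)


@dataclass
class TruthRecord:
    """Component and surplus fields the pipeline must reproduce (truth mode)."""

    cropland: AnnualField
    pasture: AnnualField
    fer_cr: AnnualField
    fer_past: AnnualField
    man_cr: AnnualField
    man_past: AnnualField
    dep_total_rate: AnnualField
    surplus_soil: dict[str, AnnualField]  # per pasture scenario name


@dataclass
class InputBundle:
    """Everything the pipeline consumes, in memory."""

    config: SyntheticConfig
    grid: GridSpec
    registry: CountryRegistry
    # land use
    snapshot_cropland: np.ndarray
    snapshot_pasture: np.ndarray
    hyde_decadal_years: np.ndarray
    hyde_decadal_cropland: np.ndarray
    hyde_decadal_pasture: np.ndarray
    hyde_annual_years: np.ndarray
    hyde_annual_cropland: np.ndarray
    hyde_annual_pasture: np.ndarray
    glc_fractions: dict[str, np.ndarray]
    fao_cropland: CountryYearTable
    fao_pasture: CountryYearTable
    # crops
    monfreda_areas: dict[str, np.ndarray]
    monfreda_production: dict[str, np.ndarray]
    fao_crop_areas: CountryCropYearTable
    fao_production: CountryCropYearTable
    einarsson_fodder_areas: CountryCropYearTable
    einarsson_fodder_production: CountryCropYearTable
    einarsson_fodder_bnf: CountryCropYearTable
    owd_yields: pd.DataFrame
    # fertilizer
    fao_fertilizer: CountryYearTable
    holland_global: pd.Series
    ifa_amounts: pd.DataFrame
    einarsson_fert_cropland_share: pd.DataFrame
    # manure
    zhang_production: AnnualField  # kg per ha of grid area, 1860-2014
    fao_manure_applied: CountryYearTable
    fao_manure_left: CountryYearTable
    einarsson_manure_applied: CountryYearTable
    einarsson_manure_left: CountryYearTable
    einarsson_manure_cropland_share: pd.DataFrame
    # deposition
    deposition_monthly: np.ndarray  # (years, 12, clat, clon), kg/ha/month
    deposition_lat: np.ndarray
    deposition_lon: np.ndarray
    deposition_year0: int = 1850
    truth: TruthRecord | None = None


# --- helpers -----------------------------------------------------------------

def smooth_field(rng: np.random.Generator, n_lat: int, n_lon: int,
                 sigma: float = 2.0) -> np.ndarray:
    """Low-pass filtered Gaussian noise squashed to (0, 1), flattened."""
    noise = gaussian_filter(rng.standard_normal((n_lat, n_lon)), sigma=sigma)
    lo, hi = noise.min(), noise.max()
    if hi - lo < 1e-12:
        return np.full(n_lat * n_lon, 0.5)
    return ((noise - lo) / (hi - lo)).ravel()


def _country_map(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Voronoi country partition with a sea margin along the eastern edge."""
    pts_r = rng.uniform(0, cfg.n_lat, cfg.n_countries)
    pts_c = rng.uniform(0, cfg.n_lon - 2, cfg.n_countries)
    rr, cc = np.meshgrid(np.arange(cfg.n_lat), np.arange(cfg.n_lon), indexing="ij")
    d = (rr[..., None] - pts_r) ** 2 + (cc[..., None] - pts_c) ** 2
    cid = d.argmin(axis=2) + 1
    cid[:, -2:] = 0  # sea margin
    return cid.ravel()


def _make_grid(cfg: SyntheticConfig) -> GridSpec:
    cid = _country_map(cfg, cfg.rng("countries"))
    return GridSpec.regular(cfg.n_lat, cfg.n_lon, lat_north=cfg.lat_north,
                            lon_west=cfg.lon_west, resolution=cfg.resolution,
                            country_id=cid)


def _registry(cfg: SyntheticConfig) -> CountryRegistry:
    reg = CountryRegistry.synthetic(cfg.n_countries)
    merge_groups = reg.merge_groups
    missing = reg.missing_before_1992
    proxy = dict(reg.proxy_map)
    ifa = reg.ifa_members
    if cfg.truth_mode or not cfg.gap_merged_countries:
        merge_groups = ()
    if cfg.truth_mode or not cfg.gap_missing_before_1992:
        missing = frozenset()
        proxy = {}
    if cfg.truth_mode:
        # every country reports its rates so rate derivation is exactly invertible
        ifa = frozenset(reg.names)
    return CountryRegistry(names=reg.names, merge_groups=merge_groups,
                           missing_before_1992=missing,
                           east_eu_donors=reg.east_eu_donors, boreal=reg.boreal,
                           eastern=reg.eastern, proxy_map=proxy, ifa_members=ifa)


def _apply_gaps(df: pd.DataFrame, registry: CountryRegistry) -> pd.DataFrame:
    """Statistical-source gap patterns: missing before 1992, merged reporting."""
    df = df.copy()
    for u in registry.missing_before_1992:
        if u in df.columns:
            df.loc[df.index < 1992, u] = np.nan
    for g in registry.merge_groups:
        members = [m for m in g.members if m in df.columns]
        if len(members) < 2:
            continue
        merged = df.index < g.split_year
        df.loc[merged, members[0]] = df.loc[merged, members].sum(axis=1)
        for m in members[1:]:
            df.loc[merged, m] = np.nan
    return df


def _temporal_multiplier(cfg: SyntheticConfig, rng: np.random.Generator,
                         country: int, kind: str) -> np.ndarray:
    """Piecewise-linear country trend over 1850-2019, equal to 1 in 2000.

    Decadal knots to 2000, annual beyond; piecewise linearity between
    decades makes the decadal history exactly invertible by linear
    interpolation.
    """
    years = np.arange(cfg.year0, cfg.year1 + 1)
    dec_years = np.arange(1700, 2001, 10)
    base = 0.35 if kind == "cropland" else 0.55
    walk = np.cumsum(rng.normal(0.02, 0.02, len(dec_years)))
    dec_vals = base + (1 - base) * (walk - walk[0]) / max(walk[-1] - walk[0], 1e-9)
    dec_vals = np.clip(dec_vals, 0.05, None)
    dec_vals[-1] = 1.0
    m = np.interp(years, dec_years, dec_vals)
    post = years > 2000
    drift = rng.normal(0.0, 0.01, post.sum()).cumsum()
    m[post] = np.clip(1.0 + drift, 0.05, None)
    # 2018-2019 clamp to 2017, mirroring the history source's coverage
    i2017 = np.searchsorted(years, 2017)
    m[i2017 + 1:] = m[i2017]
    return m


def _country_multiplier_field(grid: GridSpec, mult: dict[int, np.ndarray],
                              n_years: int) -> np.ndarray:
    out = np.ones((n_years, grid.n_cells))
    for u, m in mult.items():
        out[:, grid.country_id == u] = m[:, None]
    return out


def _noise_series(rng: np.random.Generator, years: np.ndarray,
                  lo: float = 0.8, hi: float = 1.25) -> np.ndarray:
    """Smooth multiplicative noise in [lo, hi] over time."""
    raw = gaussian_filter(rng.standard_normal(len(years)), sigma=5.0)
    span = raw.max() - raw.min()
    x = (raw - raw.min()) / span if span > 0 else np.full(len(years), 0.5)
    return lo + (hi - lo) * x


# --- main generator ----------------------------------------------------------

def generate_bundle(cfg: SyntheticConfig) -> InputBundle:
    """Generate a complete synthetic input bundle (optionally known-truth)."""
    grid = _make_grid(cfg)
    registry = _registry(cfg)
    years = np.arange(cfg.year0, cfg.year1 + 1)
    n_years = len(years)
    truth_mode = cfg.truth_mode
    land = grid.is_land

    # --- land-use snapshot (year 2000) --------------------------------------
    rng = cfg.rng("landuse")
    crop_frac = cfg.cropland_intensity * smooth_field(rng, cfg.n_lat, cfg.n_lon)
    past_frac = cfg.pasture_intensity * smooth_field(rng, cfg.n_lat, cfg.n_lon) * (1 - crop_frac)
    crop_frac[~land] = 0.0
    past_frac[~land] = 0.0
    snapshot_cropland = crop_frac * grid.cell_area
    snapshot_pasture = past_frac * grid.cell_area

    # --- temporal dynamics ---------------------------------------------------
    mult_cr = {int(u): _temporal_multiplier(cfg, cfg.rng(f"trend_cr_{u}"), int(u), "cropland")
               for u in grid.countries}
    if truth_mode:
        # identical cropland/pasture dynamics keep the implied
        # cropland:pasture splits constant in time, so the share-based
        # variants invert exactly (the share record only reaches back to 1961)
        mult_pa = mult_cr
    else:
        mult_pa = {int(u): _temporal_multiplier(cfg, cfg.rng(f"trend_pa_{u}"), int(u), "pasture")
                   for u in grid.countries}
    dyn_cr = _country_multiplier_field(grid, mult_cr, n_years)
    dyn_pa = _country_multiplier_field(grid, mult_pa, n_years)
    truth_cropland = snapshot_cropland[None, :] * dyn_cr
    truth_pasture = snapshot_pasture[None, :] * dyn_pa

    def _decadal(truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        dec_years = np.arange(1850, 2001, 10)
        dec = truth[np.searchsorted(years, dec_years)]
        ann_years = np.arange(2000, 2018)
        ann = truth[np.searchsorted(years, ann_years)]
        return dec_years, dec, ann_years, ann

    dy, hyde_dec_cr, ay, hyde_ann_cr = _decadal(truth_cropland)
    _, hyde_dec_pa, _, hyde_ann_pa = _decadal(truth_pasture)

    # --- land-cover fractions of the non-agricultural remainder -------------
    rng = cfg.rng("glc")
    raw = {k: smooth_field(rng, cfg.n_lat, cfg.n_lon) for k in
           ("forest", "natveg", "nonveg", "urban")}
    scale = {"forest": 1.0, "natveg": 0.7, "nonveg": 0.3, "urban": 0.15}
    glc = {k: raw[k] * scale[k] * land for k in raw}

    # --- country land-use tables (1961-2019) ---------------------------------
    stat_years = np.arange(1961, cfg.year1 + 1)
    si = np.searchsorted(years, stat_years)

    def _area_table(truth: np.ndarray, tag: str) -> pd.DataFrame:
        cols = {}
        for u in grid.countries:
            u = int(u)
            agg = truth[si][:, grid.country_id == u].sum(axis=1)
            noise = np.ones(len(stat_years)) if truth_mode else \
                _noise_series(cfg.rng(f"fao_{tag}_{u}"), stat_years)
            cols[u] = agg * noise
        return pd.DataFrame(cols, index=pd.Index(stat_years, name="year"))

    fao_cr_df = _area_table(truth_cropland, "cr")
    fao_pa_df = _area_table(truth_pasture, "past")
    if not truth_mode:
        fao_cr_df = _apply_gaps(fao_cr_df, registry)
        fao_pa_df = _apply_gaps(fao_pa_df, registry)

    # --- crop patterns (year 2000) -------------------------------------------
    rng = cfg.rng("crops")
    monf_areas: dict[str, np.ndarray] = {}
    monf_pro: dict[str, np.ndarray] = {}
    crop_yield = {c: rng.uniform(1500, 6000) for c in ALL_CROPS}  # kg/ha in 2000
    # country-level crop mix; fodder patterns proportional to cropland within
    # a country so area downscaling is exactly invertible
    mix = {}
    for u in grid.countries:
        w = rng.dirichlet(np.ones(len(ALL_CROPS)) * 2.0) * 0.9
        mix[int(u)] = dict(zip(ALL_CROPS, w))
    for c in ALL_CROPS:
        w_cell = np.zeros(grid.n_cells)
        for u in grid.countries:
            w_cell[grid.country_id == u] = mix[int(u)][c]
        if c in NON_FODDER_CROPS and not truth_mode:
            w_cell = w_cell * (0.5 + smooth_field(cfg.rng(f"pattern_{c}"),
                                                  cfg.n_lat, cfg.n_lon))
        monf_areas[c] = w_cell * snapshot_cropland
        yield_mod = 1.0 if truth_mode else \
            0.7 + 0.6 * smooth_field(cfg.rng(f"yield_{c}"), cfg.n_lat, cfg.n_lon)
        monf_pro[c] = monf_areas[c] * crop_yield[c] * yield_mod  # kg

    # truth crop areas follow the cropland dynamics cellwise
    dyn_rel = np.where(snapshot_cropland > 0, dyn_cr, 1.0)

    def _crop_area_truth(c: str) -> np.ndarray:
        return monf_areas[c][None, :] * dyn_rel

    def _crop_table(crops: tuple[str, ...], what: str, tag: str) -> pd.DataFrame:
        cols = {}
        for u in grid.countries:
            u = int(u)
            member = grid.country_id == u
            for c in crops:
                if what == "area":
                    agg = _crop_area_truth(c)[si][:, member].sum(axis=1)
                else:
                    # production trends follow a per-crop yield trajectory
                    traj = _yield_traj(cfg, c)[si]
                    agg = _crop_area_truth(c)[si][:, member].sum(axis=1) * \
                        crop_yield[c] * traj
                noise = np.ones(len(stat_years)) if truth_mode else \
                    _noise_series(cfg.rng(f"{tag}_{u}_{c}"), stat_years, 0.85, 1.2)
                cols[(u, c)] = agg * noise
        df = pd.DataFrame(cols, index=pd.Index(stat_years, name="year"))
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["country", "crop"])
        return df

    fao_crop_areas_df = _crop_table(NON_FODDER_CROPS, "area", "fca")
    fao_production_df = _crop_table(NON_FODDER_CROPS, "production", "fpr")
    ein_fodder_areas_df = _crop_table(FODDER_CROPS, "area", "efa")
    ein_fodder_pro_df = _crop_table(FODDER_CROPS, "production", "efp")
    rng = cfg.rng("fodder_bnf")
    fodder_bnf_rate = {c: rng.uniform(0.005, 0.03) for c in FODDER_CROPS}  # kg N / kg
    ein_fodder_bnf_df = ein_fodder_pro_df * pd.Series(
        {col: fodder_bnf_rate[col[1]] for col in ein_fodder_pro_df.columns})
    if not truth_mode:
        fao_crop_areas_df = _apply_gaps_multi(fao_crop_areas_df, registry)
        fao_production_df = _apply_gaps_multi(fao_production_df, registry)
        ein_fodder_areas_df = _apply_gaps_multi(ein_fodder_areas_df, registry)
        ein_fodder_pro_df = _apply_gaps_multi(ein_fodder_pro_df, registry)
        ein_fodder_bnf_df = _apply_gaps_multi(ein_fodder_bnf_df, registry)

    # --- wheat yield snapshots ------------------------------------------------
    rng = cfg.rng("owd")
    snap_years = [1850, 1909, 1934, 1960]
    owd_cols = {}
    reporting = list(grid.countries if truth_mode else grid.countries[:-2]) or list(grid.countries)
    for u in grid.countries:
        u = int(u)
        if u in [int(x) for x in reporting]:
            base = rng.uniform(800, 1500)
            growth = rng.uniform(1.1, 1.6)
            owd_cols[u] = [base, base * growth, base * growth**1.5, base * growth**2]
        else:
            owd_cols[u] = [np.nan] * 4
    owd_yields = pd.DataFrame(owd_cols, index=pd.Index(snap_years, name="year"))

    # --- fertilizer -----------------------------------------------------------
    rng = cfg.rng("fertilizer")
    group_rate = {g: rng.uniform(0.3, 1.2) * cfg.fertilizer_scale for g in IFA_GROUPS}
    # country fertilizer series: logistic rise-then-plateau scaled by area
    fert_cols = {}
    for u in grid.countries:
        u = int(u)
        agri = (truth_cropland + truth_pasture)[si][:, grid.country_id == u].sum(axis=1)
        ramp = 1.0 / (1.0 + np.exp(-(stat_years - 1980) / 8.0))
        noise = np.ones(len(stat_years)) if truth_mode else \
            _noise_series(cfg.rng(f"fert_{u}"), stat_years, 0.9, 1.1)
        fert_cols[u] = cfg.fertilizer_scale * agri * (0.15 + 0.85 * ramp) * noise
    fao_fert_df = pd.DataFrame(fert_cols, index=pd.Index(stat_years, name="year"))
    if not truth_mode:
        fao_fert_df = _apply_gaps(fao_fert_df, registry)
    holland_years = np.arange(1925, 1961)
    holland = pd.Series(1.0 / (1.0 + np.exp(-(holland_years - 1950) / 8.0)),
                        index=pd.Index(holland_years, name="year")) * 1e9
    # 2014/15 crop-group amounts for member countries
    ifa_rows = {}
    for u in registry.ifa_members:
        if u not in [int(x) for x in grid.countries]:
            continue
        row = {}
        member = grid.country_id == u
        for g in IFA_GROUPS:
            if g == "grassland":
                area = truth_pasture[si][stat_years == 2015][:, member].sum() + \
                    _crop_area_truth("temporary_grassland")[si][stat_years == 2015][:, member].sum()
            else:
                from .registry import IFA_GROUP_TO_CROPS
                area = sum(_crop_area_truth(c)[si][stat_years == 2015][:, member].sum()
                           for c in IFA_GROUP_TO_CROPS[g])
            row[g] = group_rate[g] * float(area)
        ifa_rows[u] = row
    ifa_amounts = pd.DataFrame(ifa_rows).T.fillna(0.0)
    rng = cfg.rng("fert_shares")
    share_cols = {}
    for u in grid.countries:
        s = 0.4 + 0.5 * _noise_series(cfg.rng(f"fshare_{u}"), stat_years, 0.0, 1.0)
        share_cols[int(u)] = np.clip(s, 0.0, 1.0)
    fert_share = pd.DataFrame(share_cols, index=pd.Index(stat_years, name="year"))

    # --- manure ---------------------------------------------------------------
    rng = cfg.rng("manure")
    prod_years = np.arange(1860, 2015)
    if truth_mode:
        # production proportional to agricultural fraction: the per-ag-ha
        # rate is uniform, so the application cap never binds
        prod_pattern = cfg.manure_scale * (snapshot_cropland + snapshot_pasture) / grid.cell_area
    else:
        prod_pattern = cfg.manure_scale * smooth_field(rng, cfg.n_lat, cfg.n_lon) * land
    ramp = 0.5 + 0.5 / (1.0 + np.exp(-(prod_years - 1960) / 20.0))
    zhang = AnnualField("Man_prod", "kg_per_ha_grid", 1860,
                        prod_pattern[None, :] * ramp[:, None])
    prod_cell = zhang.values * grid.cell_area  # kg per cell, 1860-2014
    # pad to stat years for table construction
    idx = np.clip(stat_years - 1860, 0, len(prod_years) - 1)
    prod_stat = prod_cell[idx]

    def _manure_tables(tag: str) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        app_cols, left_cols, share_cols = {}, {}, {}
        for u in grid.countries:
            u = int(u)
            agg = prod_stat[:, grid.country_id == u].sum(axis=1)
            r_app = 0.45 * (np.ones(len(stat_years)) if truth_mode else
                            _noise_series(cfg.rng(f"man_app_{tag}_{u}"), stat_years, 0.7, 1.2))
            r_left = 0.30 * (np.ones(len(stat_years)) if truth_mode else
                             _noise_series(cfg.rng(f"man_left_{tag}_{u}"), stat_years, 0.7, 1.2))
            app_cols[u] = r_app * agg
            left_cols[u] = r_left * agg
            share_cols[u] = np.clip(
                0.5 + 0.4 * (_noise_series(cfg.rng(f"man_share_{tag}_{u}"),
                                           stat_years, -1.0, 1.0)), 0.0, 1.0)
        years_ix = pd.Index(stat_years, name="year")
        return (pd.DataFrame(app_cols, index=years_ix),
                pd.DataFrame(left_cols, index=years_ix),
                pd.DataFrame(share_cols, index=years_ix))

    fao_app, fao_left, _ = _manure_tables("fao")
    ein_app, ein_left, man_share = _manure_tables("ein")
    if truth_mode:
        ein_app, ein_left = fao_app.copy(), fao_left.copy()
    if not truth_mode:
        fao_app = _apply_gaps(fao_app, registry)
        fao_left = _apply_gaps(fao_left, registry)
        ein_app = _apply_gaps(ein_app, registry)
        ein_left = _apply_gaps(ein_left, registry)

    # --- deposition -----------------------------------------------------------
    rng = cfg.rng("deposition")
    f = cfg.deposition_coarse_factor
    clat = grid.lat_centers.reshape(-1, f).mean(axis=1)
    clon = grid.lon_centers.reshape(-1, f).mean(axis=1)
    dep_years = np.arange(1850, 2015)
    spat = cfg.deposition_scale * smooth_field(rng, len(clat), len(clon)).reshape(len(clat), len(clon))
    ramp = 0.3 + 0.7 / (1.0 + np.exp(-(dep_years - 1970) / 15.0))
    season = rng.dirichlet(np.ones(12) * 4.0)
    dep_monthly = (spat[None, None, :, :] * ramp[:, None, None, None]
                   * season[None, :, None, None])

    bundle = InputBundle(
        config=cfg, grid=grid, registry=registry,
        snapshot_cropland=snapshot_cropland, snapshot_pasture=snapshot_pasture,
        hyde_decadal_years=dy, hyde_decadal_cropland=hyde_dec_cr,
        hyde_decadal_pasture=hyde_dec_pa, hyde_annual_years=ay,
        hyde_annual_cropland=hyde_ann_cr, hyde_annual_pasture=hyde_ann_pa,
        glc_fractions=glc,
        fao_cropland=CountryYearTable(fao_cr_df, units="ha"),
        fao_pasture=CountryYearTable(fao_pa_df, units="ha"),
        monfreda_areas=monf_areas, monfreda_production=monf_pro,
        fao_crop_areas=CountryCropYearTable(fao_crop_areas_df, units="ha", crops=ALL_CROPS),
        fao_production=CountryCropYearTable(fao_production_df, units="kg", crops=ALL_CROPS),
        einarsson_fodder_areas=CountryCropYearTable(ein_fodder_areas_df, units="ha", crops=ALL_CROPS),
        einarsson_fodder_production=CountryCropYearTable(ein_fodder_pro_df, units="kg", crops=ALL_CROPS),
        einarsson_fodder_bnf=CountryCropYearTable(ein_fodder_bnf_df, units="kg", crops=ALL_CROPS),
        owd_yields=owd_yields,
        fao_fertilizer=CountryYearTable(fao_fert_df, units="kg"),
        holland_global=holland,
        ifa_amounts=ifa_amounts,
        einarsson_fert_cropland_share=fert_share,
        zhang_production=zhang,
        fao_manure_applied=CountryYearTable(fao_app, units="kg"),
        fao_manure_left=CountryYearTable(fao_left, units="kg"),
        einarsson_manure_applied=CountryYearTable(ein_app, units="kg"),
        einarsson_manure_left=CountryYearTable(ein_left, units="kg"),
        einarsson_manure_cropland_share=man_share,
        deposition_monthly=dep_monthly, deposition_lat=clat, deposition_lon=clon,
        deposition_year0=1850,
    )
    if truth_mode:
        truth, fert_share_t, man_share_t = _compute_truth(
            cfg, grid, registry, truth_cropland, truth_pasture, glc,
            monf_areas, monf_pro, dyn_rel, crop_yield, fodder_bnf_rate,
            fao_production_df, ein_fodder_pro_df, owd_yields,
            group_rate, fao_fert_df, holland, prod_cell,
            dep_monthly, clat, clon)
        bundle.truth = truth
        bundle.einarsson_fert_cropland_share = fert_share_t
        bundle.einarsson_manure_cropland_share = man_share_t
    return bundle


def _yield_traj(cfg: SyntheticConfig, crop: str) -> np.ndarray:
    """Relative yield trajectory over 1850-2019, equal to 1 in 2000."""
    years = np.arange(cfg.year0, cfg.year1 + 1)
    ramp = 0.25 + 0.75 / (1.0 + np.exp(-(years - 1970) / 15.0))
    return ramp / ramp[np.searchsorted(years, 2000)]


def _apply_gaps_multi(df: pd.DataFrame, registry: CountryRegistry) -> pd.DataFrame:
    df = df.copy()
    for u in registry.missing_before_1992:
        cols = [c for c in df.columns if c[0] == u]
        df.loc[df.index < 1992, cols] = np.nan
    for g in registry.merge_groups:
        members = [m for m in g.members]
        crops = sorted({c for uu, c in df.columns if uu in members})
        merged = df.index < g.split_year
        for c in crops:
            have = [(m, c) for m in members if (m, c) in df.columns]
            if len(have) < 2:
                continue
            df.loc[merged, have[0]] = df.loc[merged, have].sum(axis=1)
            for col in have[1:]:
                df.loc[merged, col] = np.nan
    return df


def _compute_truth(cfg, grid, registry, truth_cropland, truth_pasture, glc,
                   monf_areas, monf_pro, dyn_rel, crop_yield, fodder_bnf_rate,
                   fao_production_df, ein_fodder_pro_df, owd_yields,
                   group_rate, fao_fert_df, holland, prod_cell,
                   dep_monthly, clat, clon):
    """Truth component and surplus fields by direct forward algebra.

    Written as plain per-cell formulas, independent of the pipeline's
    generic harmonization/downscaling machinery, so the end-to-end
    recovery check is meaningful.  Returns the truth record plus the
    cropland-share tables implied by the rate-based fertilizer split and
    the uniform manure split (so the share-based variants coincide with
    them on a truth bundle).
    """
    from .coefficients import DEFAULT_COEFFICIENTS as coeffs
    from .registry import IFA_GROUP_TO_CROPS, ifa_group_of

    years = np.arange(cfg.year0, cfg.year1 + 1)
    n_years = len(years)
    stat_years = np.arange(1961, cfg.year1 + 1)
    countries = [int(u) for u in grid.countries]
    member = {u: grid.country_id == u for u in countries}

    # land use
    agri = truth_cropland + truth_pasture
    nonagri = np.maximum(grid.cell_area[None, :] - agri, 0.0)
    raw = np.stack([glc[k] for k in ("forest", "natveg", "nonveg", "urban")])
    tot = raw.sum(axis=0)
    rel = np.where(tot > 0, raw / np.where(tot > 0, tot, 1.0), 0.0)
    rel[1, tot == 0] = 1.0
    a_for, a_natveg, a_nonveg, a_urban = (nonagri * r for r in rel)

    # crop areas (ha per cell per year)
    area_truth = {c: monf_areas[c][None, :] * dyn_rel for c in ALL_CROPS}

    # country production over the full span (kg)
    pro_stat = pd.concat([fao_production_df, ein_fodder_pro_df], axis=1)
    snap_years = owd_yields.index.to_numpy(int)
    early_years = np.arange(cfg.year0, 1961)
    pro_country = {}
    wheat_owd = {}
    for u in countries:
        warea = area_truth["wheat"][:, member[u]].sum(axis=1)
        y_interp = np.interp(early_years, snap_years, owd_yields[u].to_numpy(float))
        wheat_owd[u] = y_interp * warea[: len(early_years)]
    for u in countries:
        w61 = float(pro_stat.at[1961, (u, "wheat")])
        for c in ALL_CROPS:
            s = np.empty(n_years)
            s[len(early_years):] = pro_stat[(u, c)].to_numpy(float)
            if c == "wheat":
                s[: len(early_years)] = wheat_owd[u]
            else:
                ratio = wheat_owd[u] / w61 if w61 > 0 else np.ones(len(early_years))
                s[: len(early_years)] = ratio * float(pro_stat.at[1961, (u, c)])
            pro_country[(u, c)] = s

    # gridded production via static year-2000 spatial shares
    pro_grid = {}
    for c in ALL_CROPS:
        v = np.zeros((n_years, grid.n_cells))
        for u in countries:
            w = monf_pro[c][member[u]]
            tot_w = w.sum()
            if tot_w > 0:
                v[:, member[u]] = pro_country[(u, c)][:, None] * (w / tot_w)[None, :]
        pro_grid[c] = v

    # fertilizer: group rates x areas, one adjustment scalar per country-year
    grass_rate = group_rate["grassland"]
    unadj_cr = np.zeros((n_years, grid.n_cells))
    for c in NON_FODDER_CROPS:
        unadj_cr += group_rate[ifa_group_of(c)] * area_truth[c]
    for c in FODDER_CROPS:
        unadj_cr += grass_rate * area_truth[c]
    unadj_past = grass_rate * truth_pasture
    # pre-statistical trend: zero through 1920, bridge, anchored global trend
    h_last = float(holland.loc[holland.index.max()])
    trend = np.zeros(len(early_years))
    for k, y in enumerate(early_years):
        if y <= 1920:
            trend[k] = 0.0
        elif y < holland.index.min():
            trend[k] = (y - 1920) / (holland.index.min() - 1920) * \
                float(holland.loc[holland.index.min()]) / h_last
        else:
            trend[k] = float(holland.loc[min(y, holland.index.max())]) / h_last
    fer_cr = np.zeros_like(unadj_cr)
    fer_past = np.zeros_like(unadj_past)
    for u in countries:
        target = np.empty(n_years)
        target[len(early_years):] = fao_fert_df[u].to_numpy(float)
        target[: len(early_years)] = trend * float(fao_fert_df.at[1961, u])
        unadj = unadj_cr[:, member[u]].sum(axis=1) + unadj_past[:, member[u]].sum(axis=1)
        f = np.where(unadj > 0, target / np.where(unadj > 0, unadj, 1.0), 0.0)
        fer_cr[:, member[u]] = f[:, None] * unadj_cr[:, member[u]]
        fer_past[:, member[u]] = f[:, None] * unadj_past[:, member[u]]

    # manure: constant source ratios on the padded production grid
    prod_idx = np.clip(years - 1860, 0, prod_cell.shape[0] - 1)
    prod_pad = prod_cell[prod_idx]
    man_app = 0.45 * prod_pad
    man_left = 0.30 * prod_pad
    w_cr = np.where(agri > 0, truth_cropland / np.where(agri > 0, agri, 1.0), 0.0)
    man_cr = man_app * w_cr
    man_past = man_app * (1 - w_cr) + man_left

    # deposition: nearest coarse neighbour, annual sums, clamp after source end
    annual_coarse = dep_monthly.sum(axis=1)
    ilat = np.abs(grid.lat_centers[:, None] - clat[None, :]).argmin(axis=1)
    ilon = np.abs(grid.lon_centers[:, None] - clon[None, :]).argmin(axis=1)
    fine = annual_coarse[:, ilat[:, None], ilon[None, :]].reshape(len(annual_coarse), -1)
    dep_rate = fine[np.clip(years - 1850, 0, len(annual_coarse) - 1)]
    # kg per cell for land type x = rate (kg/ha of grid) x area_x (ha)
    dep_cr = dep_rate * truth_cropland
    dep_past = dep_rate * truth_pasture
    dep_for = dep_rate * a_for
    dep_natveg = dep_rate * a_natveg
    dep_nonveg = dep_rate * a_nonveg
    dep_urban = dep_rate * a_urban

    # biological fixation
    bnf_cr = sum(coeffs.bnf_crop_rate[c] * area_truth[c] for c in coeffs.bnf_crop_rate)
    for c in FODDER_CROPS:
        bnf_cr = bnf_cr + fodder_bnf_rate[c] * pro_grid[c]
    bnf_past = coeffs.bnf_pasture * truth_pasture
    forest_rate = np.full(grid.n_cells, coeffs.bnf_forest_temperate)
    for u in registry.boreal:
        forest_rate[grid.country_id == u] = coeffs.bnf_forest_boreal
    bnf_for = forest_rate[None, :] * a_for
    bnf_natveg = coeffs.bnf_natveg * a_natveg

    # removals and surplus per pasture scenario
    rem_cr = sum(pro_grid[c] / 1000.0 * coeffs.n_content[c] for c in NON_FODDER_CROPS)
    rem_for = coeffs.forest_removal_rate * dep_for
    inp_cr = fer_cr + man_cr + dep_cr + bnf_cr
    inp_past = fer_past + man_past + dep_past + bnf_past
    surp_fixed = (dep_for + bnf_for - rem_for) + (dep_natveg + bnf_natveg) + \
        dep_nonveg + dep_urban + (inp_cr - rem_cr)
    from .coefficients import PASTURE_SCENARIOS
    surplus = {}
    for name, scen in PASTURE_SCENARIOS.items():
        c_cell = np.empty(grid.n_cells)
        for u in countries:
            c_cell[member[u]] = scen.coefficient(u in registry.eastern)
        c_cell[grid.country_id == 0] = 0.0
        rem_past = np.maximum(
            c_cell[None, :] * (inp_past - scen.n_losses * man_past), 0.0)
        surplus[name] = AnnualField(
            f"Surp_soil_{name}", "kg_per_cell", cfg.year0,
            surp_fixed + inp_past - rem_past)

    # shares implied by the rate-based fertilizer and uniform manure splits
    f_share, m_share = {}, {}
    for u in countries:
        tc = fer_cr[:, member[u]].sum(axis=1)
        tp = fer_past[:, member[u]].sum(axis=1)
        tot_f = tc + tp
        f_share[u] = np.where(tot_f > 0, tc / np.where(tot_f > 0, tot_f, 1.0), 0.5)
        ac = man_cr[:, member[u]].sum(axis=1)
        aa = man_app[:, member[u]].sum(axis=1)
        m_share[u] = np.where(aa > 0, ac / np.where(aa > 0, aa, 1.0), 0.5)
    six = n_years - len(stat_years)
    ix = pd.Index(stat_years, name="year")
    fert_share_t = pd.DataFrame({u: f_share[u][six:] for u in countries}, index=ix)
    man_share_t = pd.DataFrame({u: m_share[u][six:] for u in countries}, index=ix)

    truth = TruthRecord(
        cropland=AnnualField("truth_cropland", "ha", cfg.year0, truth_cropland),
        pasture=AnnualField("truth_pasture", "ha", cfg.year0, truth_pasture),
        fer_cr=AnnualField("truth_fer_cr", "kg_per_cell", cfg.year0, fer_cr),
        fer_past=AnnualField("truth_fer_past", "kg_per_cell", cfg.year0, fer_past),
        man_cr=AnnualField("truth_man_cr", "kg_per_cell", cfg.year0, man_cr),
        man_past=AnnualField("truth_man_past", "kg_per_cell", cfg.year0, man_past),
        dep_total_rate=AnnualField("truth_dep_rate", "kg_per_ha_grid", cfg.year0, dep_rate),
        surplus_soil=surplus,
    )
    return truth, fert_share_t, man_share_t
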