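"""Fertilizer: series completion, rates, gridding adjustment, partitioning."""

import numpy as np
import pandas as pd
import pytest

import nsurplus as ns
from nsurplus.fertilizer import (FertilizerApproach, complete_country_fertilizer,
                                 derive_ifa_rates, fill_country_shares,
                                 grid_and_adjust, partition_fertilizer)
from nsurplus.fields import AnnualField, CountryYearTable
from nsurplus.registry import CountryRegistry


def _simple_registry(**kw):
    defaults = dict(names={1: "C01", 2: "C02", 3: "C03"})
    defaults.update(kw)
    return CountryRegistry(**defaults)


class TestCountrySeries:
    def _table(self, values=None):
        years = np.arange(1961, 2020)
        if values is None:
            values = np.full(len(years), 1000.0)
        return CountryYearTable(pd.DataFrame({1: values}, index=years), units="kg")

    def test_zero_fertilizer_before_1920(self):
        holland = pd.Series(np.linspace(1, 5, 36), index=np.arange(1925, 1961))
        out = complete_country_fertilizer(self._table(), holland, _simple_registry())
        assert (out.df.loc[:1920, 1] == 0).all()
        assert out.df.at[1900, 1] == 0.0

    def test_flat_global_trend_gives_flat_country_series(self):
        holland = pd.Series(np.full(36, 3.0), index=np.arange(1925, 1961))
        out = complete_country_fertilizer(self._table(), holland, _simple_registry())
        np.testing.assert_allclose(out.df.loc[1925:1960, 1].to_numpy(), 1000.0)

    def test_bridge_years_interpolate_from_zero(self):
        holland = pd.Series(np.full(36, 3.0), index=np.arange(1925, 1961))
        out = complete_country_fertilizer(self._table(), holland, _simple_registry())
        # 1920 -> 0; 1925 -> full trend value; linear in between
        assert out.df.at[1920, 1] == 0.0
        assert out.df.at[1923, 1] == pytest.approx(1000.0 * 3 / 5)

    def test_missing_country_filled_with_donor_dynamics(self):
        years = np.arange(1961, 2020)
        donors = {u: np.linspace(100, 400, len(years)) for u in (2, 3)}
        flagged = np.where(years < 1992, np.nan, 500.0)
        df = pd.DataFrame({1: flagged, **donors}, index=years)
        reg = _simple_registry(missing_before_1992=frozenset({1}),
                               east_eu_donors=frozenset({2, 3}))
        holland = pd.Series(np.full(36, 1.0), index=np.arange(1925, 1961))
        out = complete_country_fertilizer(CountryYearTable(df, units="kg"),
                                          holland, reg)
        # hand arithmetic: donor total dynamics anchored at 1992
        e = donors[2] + donors[3]
        want = e[1970 - 1961] / e[1992 - 1961] * 500.0
        assert out.df.at[1970, 1] == pytest.approx(want, rel=1e-12)

    def test_entirely_missing_donor_pool_is_an_error(self):
        years = np.arange(1961, 2020)
        flagged = np.where(years < 1992, np.nan, 500.0)
        df = pd.DataFrame({1: flagged}, index=years)
        reg = _simple_registry(missing_before_1992=frozenset({1}),
                               east_eu_donors=frozenset())
        holland = pd.Series(np.full(36, 1.0), index=np.arange(1925, 1961))
        with pytest.raises(ValueError, match="donor"):
            complete_country_fertilizer(CountryYearTable(df, units="kg"),
                                        holland, reg)


class TestRates:
    def test_rate_is_amount_over_area(self):
        reg = _simple_registry(ifa_members=frozenset({1}))
        amounts = pd.DataFrame({"wheat": [100.0], "grassland": [60.0]}, index=[1])
        areas = pd.DataFrame({"wheat": [50.0]}, index=[1])
        grass = pd.Series({1: 30.0})
        rates = derive_ifa_rates(amounts, areas, grass, reg)
        assert rates.crop_rate.at[1, "wheat"] == pytest.approx(2.0)
        assert rates.grass_rate.at[1] == pytest.approx(2.0)

    def test_non_member_country_gets_pooled_rates(self):
        reg = _simple_registry(ifa_members=frozenset({1}))
        amounts = pd.DataFrame({"wheat": [100.0], "grassland": [60.0]}, index=[1])
        areas = pd.DataFrame({"wheat": [50.0]}, index=[1, 2])
        grass = pd.Series({1: 30.0, 2: 10.0})
        rates = derive_ifa_rates(amounts, areas, grass, reg)
        assert rates.crop_rate.at[2, "wheat"] == rates.crop_rate.at[1, "wheat"]
        assert rates.grass_rate.at[2] == rates.grass_rate.at[1]

    def test_zero_area_with_positive_amount_is_an_error(self):
        reg = _simple_registry(ifa_members=frozenset({1}))
        amounts = pd.DataFrame({"wheat": [100.0], "grassland": [0.0]}, index=[1])
        areas = pd.DataFrame({"wheat": [0.0]}, index=[1])
        with pytest.raises(ValueError, match="zero harvested area"):
            derive_ifa_rates(amounts, areas, pd.Series({1: 10.0}), reg)


class TestAdjustment:
    def test_matching_aggregate_means_factor_one(self, components, bundle):
        """After adjustment, country sums equal the completed country series."""
        grid = bundle.grid
        fer = components.fertilizer[FertilizerApproach.IFA]
        total = fer.fer_cr.values + fer.fer_past.values
        for u in grid.countries:
            got = total[:, grid.country_id == u].sum(axis=1)
            want = components.nfer_soil.df[int(u)].to_numpy()
            np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_scaling_country_series_scales_gridded_output(self):
        """Monotone response: doubling the target doubles both outputs."""
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        from nsurplus.fertilizer import FertilizerRates
        rates = FertilizerRates(
            crop_rate=pd.DataFrame({c: [1.0] for c in ns.NON_FODDER_CROPS}, index=[1]),
            grass_rate=pd.Series({1: 1.0}))
        areas = {c: AnnualField(c, "ha", 2000, np.full((2, 2), 1.0))
                 for c in ("wheat",)}
        pasture = AnnualField("pa", "ha", 2000, np.full((2, 2), 1.0))
        agri = AnnualField("ag", "ha", 2000, np.full((2, 2), 2.0))
        years = pd.Index([2000, 2001], name="year")
        t1 = CountryYearTable(pd.DataFrame({1: [10.0, 10.0]}, index=years), units="kg")
        t2 = CountryYearTable(pd.DataFrame({1: [20.0, 20.0]}, index=years), units="kg")
        cr1, pa1 = grid_and_adjust(rates, areas, {}, pasture, agri, t1, grid)
        cr2, pa2 = grid_and_adjust(rates, areas, {}, pasture, agri, t2, grid)
        np.testing.assert_allclose(cr2.values, 2 * cr1.values, rtol=1e-12)
        np.testing.assert_allclose(pa2.values, 2 * pa1.values, rtol=1e-12)


class TestPartition:
    def test_zero_pasture_sends_everything_to_cropland(self):
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        fer_cr = AnnualField("fc", "kg_per_cell", 2000, np.array([[6.0, 4.0]]))
        fer_past = AnnualField("fp", "kg_per_cell", 2000, np.zeros((1, 2)))
        cropland = AnnualField("cr", "ha", 2000, np.ones((1, 2)))
        pasture = AnnualField("pa", "ha", 2000, np.zeros((1, 2)))
        shares = pd.DataFrame({1: [1.0]}, index=pd.Index([2000], name="year"))
        for approach in FertilizerApproach:
            out = partition_fertilizer(fer_cr, fer_past, approach, grid,
                                       cropland, pasture, shares)
            assert out.fer_past.values.sum() == pytest.approx(0.0)
            assert out.fer_cr.values.sum() == pytest.approx(10.0)

    def test_share_based_split_hits_the_given_shares(self):
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        fer_cr = AnnualField("fc", "kg_per_cell", 2000, np.array([[30.0, 30.0]]))
        fer_past = AnnualField("fp", "kg_per_cell", 2000, np.array([[20.0, 20.0]]))
        cropland = AnnualField("cr", "ha", 2000, np.ones((1, 2)))
        pasture = AnnualField("pa", "ha", 2000, np.ones((1, 2)))
        shares = pd.DataFrame({1: [0.8]}, index=pd.Index([2000], name="year"))
        out = partition_fertilizer(fer_cr, fer_past,
                                   FertilizerApproach.EINARSSON_SHARES, grid,
                                   cropland, pasture, shares)
        assert out.fer_cr.values.sum() == pytest.approx(80.0)
        assert out.fer_past.values.sum() == pytest.approx(20.0)

    def test_country_totals_identical_across_approaches(self, components, bundle):
        grid = bundle.grid
        a = components.fertilizer[FertilizerApproach.IFA]
        b = components.fertilizer[FertilizerApproach.EINARSSON_SHARES]
        tot_a = a.fer_cr.values + a.fer_past.values
        tot_b = b.fer_cr.values + b.fer_past.values
        for u in grid.countries:
            cells = grid.country_id == u
            np.testing.assert_allclose(tot_a[:, cells].sum(axis=1),
                                       tot_b[:, cells].sum(axis=1), rtol=1e-9)

    def test_rate_based_split_on_one_cell_matches_hand_arithmetic(self):
        """Adjusted rate x area, cropland term plus fodder at the grass rate."""
        grid = ns.GridSpec.regular(1, 1, country_id=np.array([1]))
        from nsurplus.fertilizer import FertilizerRates
        rates = FertilizerRates(
            crop_rate=pd.DataFrame({c: [0.0] for c in ns.NON_FODDER_CROPS}, index=[1])
            .assign(wheat=2.0),
            grass_rate=pd.Series({1: 3.0}))
        areas = {"wheat": AnnualField("wheat", "ha", 2000, np.array([[5.0]]))}
        fodder = {"lucerne": AnnualField("lucerne", "ha", 2000, np.array([[2.0]]))}
        pasture = AnnualField("pa", "ha", 2000, np.array([[4.0]]))
        agri = AnnualField("ag", "ha", 2000, np.array([[11.0]]))
        # unadjusted: 2*5 + 3*2 (cropland) and 3*4 (pasture) = 16 + 12 = 28
        table = CountryYearTable(pd.DataFrame({1: [28.0]},
                                              index=pd.Index([2000], name="year")),
                                 units="kg")
        cr, pa = grid_and_adjust(rates, areas, fodder, pasture, agri, table, grid)
        assert cr.values[0, 0] == pytest.approx(16.0)
        assert pa.values[0, 0] == pytest.approx(12.0)


class TestShareFilling:
    def test_proxy_then_donor_mean_fallbacks(self):
        years = pd.Index([2000, 2001], name="year")
        shares = pd.DataFrame({2: [0.6, 0.6], 3: [0.4, 0.4],
                               4: [np.nan, np.nan]}, index=years)
        reg = CountryRegistry(names={u: f"C{u:02d}" for u in range(1, 5)},
                              proxy_map={4: 2},
                              east_eu_donors=frozenset({3}))
        out = fill_country_shares(shares, reg, [1, 2, 3, 4])
        assert (out[4] == 0.6).all()      # proxy wins
        assert (out[1] == 0.4).all()      # absent country: donor mean
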