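"""Land-use reconstruction: interpolation, harmonization, consistency, closure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nsurplus as ns
from nsurplus.fields import AnnualField, CountryYearTable
from nsurplus.landuse import (apply_snapshot, decompose_nonagricultural,
                              enforce_physical_consistency, harmonize_to_country,
                              interpolate_decadal, temporal_ratio)
from nsurplus.redistribute import CapacityError, redistribute_equal_spare
from nsurplus.registry import CountryRegistry


class TestInterpolateDecadal:
    def test_linear_midpoint_between_knots(self):
        out = interpolate_decadal(
            np.array([1990, 2000]), np.array([[100.0], [200.0]]),
            np.array([2000]), np.array([[200.0]]), 1990, 2000)
        assert out[1995 - 1990, 0] == pytest.approx(150.0)

    def test_constant_knots_give_constant_series(self):
        out = interpolate_decadal(
            np.arange(1850, 2001, 10), np.full((16, 1), 7.0),
            np.arange(2000, 2018), np.full((18, 1), 7.0))
        assert (out == 7.0).all()

    def test_2018_and_2019_clamped_to_2017(self):
        annual_years = np.arange(2000, 2018)
        annual = np.linspace(10, 27, 18)[:, None]
        out = interpolate_decadal(
            np.array([1850, 2000]), np.array([[5.0], [10.0]]),
            annual_years, annual)
        assert out[2018 - 1850, 0] == out[2017 - 1850, 0] == 27.0
        assert out[2019 - 1850, 0] == 27.0

    def test_non_monotone_years_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            interpolate_decadal(np.array([2000, 1990]), np.ones((2, 1)),
                                np.array([2000]), np.ones((1, 1)))


class TestTemporalRatio:
    def test_constant_series_gives_unit_ratio(self):
        f = AnnualField("a", "ha", 1998, np.full((4, 2), 3.0))
        r = temporal_ratio(f)
        assert (r.values == 1.0).all()

    def test_half_reference_gives_half_ratio(self):
        vals = np.array([[50.0], [100.0]])
        f = AnnualField("a", "ha", 1999, vals)
        assert temporal_ratio(f).values[0, 0] == pytest.approx(0.5)

    def test_zero_reference_carries_value_unchanged(self, caplog):
        f = AnnualField("a", "ha", 1999, np.array([[4.0], [0.0]]))
        r = temporal_ratio(f)
        assert r.values[0, 0] == 1.0 and r.values[1, 0] == 1.0


class TestApplySnapshot:
    def test_unit_ratio_reproduces_snapshot_every_year(self):
        ratio = AnnualField("r", "dimensionless", 2000, np.ones((3, 2)))
        out = apply_snapshot(np.array([5.0, 9.0]), ratio, "A")
        assert (out.values == np.array([5.0, 9.0])).all()

    def test_zero_snapshot_stays_zero(self):
        ratio = AnnualField("r", "dimensionless", 2000, np.full((3, 2), 2.0))
        out = apply_snapshot(np.zeros(2), ratio, "A")
        assert (out.values == 0).all()

    def test_matches_cellwise_loop_oracle(self):
        rng = np.random.default_rng(1)
        snap = rng.uniform(0, 10, 4)
        ratio = AnnualField("r", "dimensionless", 2000, rng.uniform(0.5, 2, (3, 4)))
        out = apply_snapshot(snap, ratio, "A")
        for t in range(3):
            for i in range(4):
                assert out.values[t, i] == pytest.approx(snap[i] * ratio.values[t, i])


def _registry_two():
    return CountryRegistry(names={1: "C01", 2: "C02"})


class TestHarmonization:
    def _field(self, grid, year0=1960, n_years=4):
        rng = np.random.default_rng(0)
        return AnnualField("A_cr", "ha",
                           year0, rng.uniform(1, 5, (n_years, grid.n_cells)))

    def test_doubling_table_doubles_every_cell(self):
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        f = AnnualField("A", "ha", 1961, np.array([[2.0, 3.0]]))
        table = CountryYearTable(pd.DataFrame({1: [10.0]}, index=[1961]), units="ha")
        out = harmonize_to_country(f, table, grid, _registry_two())
        np.testing.assert_allclose(out.values, [[4.0, 6.0]])

    def test_country_sums_match_table_everywhere(self):
        grid = ns.GridSpec.regular(2, 3, country_id=np.array([1, 1, 2, 2, 1, 2]))
        rng = np.random.default_rng(2)
        f = AnnualField("A", "ha", 1961, rng.uniform(1, 5, (59, 6)))
        years = np.arange(1961, 2020)
        table = CountryYearTable(pd.DataFrame(
            {1: rng.uniform(5, 20, 59), 2: rng.uniform(5, 20, 59)}, index=years),
            units="ha")
        out = harmonize_to_country(f, table, grid, _registry_two())
        for u in (1, 2):
            cells = grid.country_id == u
            for t, y in enumerate(years):
                # loop-based aggregation oracle
                want = table.df.at[y, u]
                got = sum(out.values[t, i] for i in np.flatnonzero(cells))
                assert got == pytest.approx(want, rel=1e-9)

    def test_pre_1961_years_use_the_1961_ratio(self):
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        f = AnnualField("A", "ha", 1955, np.ones((10, 2)))
        table = CountryYearTable(pd.DataFrame({1: np.full(59, 6.0)},
                                              index=np.arange(1961, 2020)), units="ha")
        out = harmonize_to_country(f, table, grid, _registry_two())
        # 1961 ratio is 3; 1955-1960 must be scaled by 3 as well
        np.testing.assert_allclose(out.values[:6], 3.0)

    def test_flagged_country_uses_1992_ratio_before_1992(self):
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        reg = CountryRegistry(names={1: "C01"}, missing_before_1992=frozenset({1}))
        f = AnnualField("A", "ha", 1980, np.ones((40, 2)))
        years = np.arange(1961, 2020)
        vals = np.where(years < 1992, np.nan, 8.0)
        table = CountryYearTable(pd.DataFrame({1: vals}, index=years), units="ha")
        out = harmonize_to_country(f, table, grid, reg)
        # 1992 ratio is 4; all pre-1992 years share it
        np.testing.assert_allclose(out.values[: 1992 - 1980], 4.0)

    def test_positive_table_with_zero_grid_is_an_error(self):
        grid = ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
        f = AnnualField("A", "ha", 1961, np.zeros((1, 2)))
        table = CountryYearTable(pd.DataFrame({1: [5.0]}, index=[1961]), units="ha")
        with pytest.raises(ValueError, match="no gridded area"):
            harmonize_to_country(f, table, grid, _registry_two())


class TestPhysicalConsistency:
    def test_under_capacity_is_identity(self, two_cell_grid):
        cr = AnnualField("cr", "ha", 2000, np.array([[1.0, 2.0]]))
        pa = AnnualField("pa", "ha", 2000, np.array([[0.5, 0.5]]))
        out_cr, out_pa = enforce_physical_consistency(cr, pa, two_cell_grid)
        np.testing.assert_array_equal(out_cr.values, cr.values)
        np.testing.assert_array_equal(out_pa.values, pa.values)

    def test_hand_redistribution_two_cells(self):
        """Areas (120, 10) against capacities (100, 100) become (100, 30)."""
        values, _ = redistribute_equal_spare(
            np.array([120.0, 10.0]), np.array([100.0, 100.0]))
        np.testing.assert_allclose(values, [100.0, 30.0])

    def test_overfull_country_is_an_error(self):
        with pytest.raises(CapacityError):
            redistribute_equal_spare(np.array([150.0, 60.0]), np.array([100.0, 100.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_random_instances_conserve_and_respect_capacity(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        capacity = rng.uniform(5, 20, n)
        values = rng.uniform(0, 12, n)
        if values.sum() > capacity.sum():
            values *= 0.9 * capacity.sum() / values.sum()
        comp_a = values * rng.uniform(0, 1, n)
        comp_b = values - comp_a
        out, (a, b) = redistribute_equal_spare(values, capacity, (comp_a, comp_b))
        assert (out <= capacity + 1e-9).all()
        assert out.sum() == pytest.approx(values.sum(), rel=1e-12)
        assert a.sum() == pytest.approx(comp_a.sum(), rel=1e-9)
        assert b.sum() == pytest.approx(comp_b.sum(), rel=1e-9)
        np.testing.assert_allclose(a + b, out, rtol=1e-9, atol=1e-12)

    def test_country_totals_preserved_through_correction(self):
        grid = ns.GridSpec.regular(2, 2, country_id=np.array([1, 1, 1, 1]))
        area = grid.cell_area
        cr = AnnualField("cr", "ha", 2000, np.array([[1.4 * area[0], 0.1 * area[1],
                                                      0.1 * area[2], 0.1 * area[3]]]))
        pa = AnnualField("pa", "ha", 2000, np.array([[0.2 * area[0], 0.1 * area[1],
                                                      0.1 * area[2], 0.1 * area[3]]]))
        out_cr, out_pa = enforce_physical_consistency(cr, pa, grid)
        assert out_cr.values.sum() == pytest.approx(cr.values.sum(), rel=1e-12)
        assert out_pa.values.sum() == pytest.approx(pa.values.sum(), rel=1e-12)
        assert ((out_cr.values + out_pa.values) <= area * (1 + 1e-12)).all()


class TestDecomposition:
    def test_pure_forest_fraction_takes_all(self):
        non_agri = AnnualField("na", "ha", 2000, np.array([[10.0]]))
        out = decompose_nonagricultural(non_agri, {
            "forest": np.array([0.4]), "natveg": np.array([0.0]),
            "nonveg": np.array([0.0]), "urban": np.array([0.0])})
        assert out["forest"].values[0, 0] == pytest.approx(10.0)

    def test_components_sum_to_non_agricultural(self):
        rng = np.random.default_rng(3)
        non_agri = AnnualField("na", "ha", 2000, rng.uniform(0, 5, (4, 6)))
        fr = {k: rng.uniform(0, 1, 6) for k in ("forest", "natveg", "nonveg", "urban")}
        out = decompose_nonagricultural(non_agri, fr)
        total = sum(f.values for f in out.values())
        np.testing.assert_allclose(total, non_agri.values, rtol=1e-12)

    def test_zero_fractions_assign_residual_to_natveg(self):
        non_agri = AnnualField("na", "ha", 2000, np.array([[7.0]]))
        out = decompose_nonagricultural(non_agri, {
            k: np.array([0.0]) for k in ("forest", "natveg", "nonveg", "urban")})
        assert out["natveg"].values[0, 0] == pytest.approx(7.0)


class TestClosure:
    def test_land_types_partition_the_cell_area(self, components, bundle):
        lu = components.landuse
        total = (lu.cropland.values + lu.pasture.values + lu.forest.values +
                 lu.natveg.values + lu.nonveg.values + lu.urban.values)
        np.testing.assert_allclose(total, np.broadcast_to(
            bundle.grid.cell_area, total.shape), rtol=1e-9)

    def test_country_pinning_survives_consistency_correction(self, components, bundle):
        lu, grid = components.landuse, bundle.grid
        table = bundle.fao_cropland.df
        reg = bundle.registry
        for u in grid.countries:
            u = int(u)
            if u in reg.missing_before_1992 or reg.merge_group_of(u):
                continue
            got = lu.cropland.country_sum(grid, u)
            for y in (1961, 1990, 2019):
                want = table.at[y, u]
                t = y - lu.cropland.year0
                assert got[t] == pytest.approx(want, rel=1e-9)
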