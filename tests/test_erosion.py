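"""Erosivity, erodibility, curve-number runoff and RUSLE yields."""

import numpy as np
import pytest

from reefshed import erosion as ero
from reefshed.datatypes import BARE, FOREST, HSG_A, HSG_D
from reefshed.erosion import ErosivityModel, RusleFactors


class TestMfi:
    def test_uniform_rain_equals_monthly_amount(self):
        assert ero.mfi(np.full(12, 100.0)) == pytest.approx(100.0)

    def test_single_wet_month_equals_annual_total(self):
        p = np.zeros(12)
        p[1] = 600.0
        assert ero.mfi(p) == pytest.approx(600.0)

    def test_hand_value(self):
        p = np.zeros(12)
        p[0], p[1] = 200.0, 100.0
        assert ero.mfi(p) == pytest.approx((40000 + 10000) / 300, rel=1e-12)

    def test_all_zero_year_is_zero(self):
        assert ero.mfi(np.zeros(12)) == 0.0

    def test_gridded_and_negative(self):
        grid = np.full((12, 2, 2), 50.0)
        np.testing.assert_allclose(ero.mfi(grid), 50.0)
        with pytest.raises(ValueError):
            ero.mfi(-grid)


class TestErosivity:
    def test_identity_coefficients(self):
        model = ErosivityModel(a=1.0, b=1.0)
        np.testing.assert_allclose(ero.erosivity_from_mfi(np.array([0.0, 3.0]), model),
                                   [0.0, 3.0])

    def test_calculator_value(self):
        model = ErosivityModel(a=0.5, b=1.2)
        assert ero.erosivity_from_mfi(100.0, model) == pytest.approx(0.5 * 100**1.2)

    def test_nonpositive_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ErosivityModel(a=-1.0, b=1.0)


class TestKFactor:
    def test_sandy_organic_soil_resists_erosion(self):
        # coarse, carbon-rich: the low-K "high resistance" band
        k = ero.k_factor(sand=80.0, silt=12.0, clay=8.0, org_carbon=3.0)
        assert 0.0 < k < 0.2

    def test_silty_poor_soil_erodes_easily(self):
        k = ero.k_factor(sand=5.0, silt=85.0, clay=10.0, org_carbon=0.1)
        assert k >= 0.4

    def test_matches_published_formula_by_hand(self):
        sa, si, cl, oc = 30.0, 40.0, 30.0, 1.5
        f1 = 0.2 + 0.3 * np.exp(-0.0256 * sa * (1 - si / 100))
        f2 = (si / (cl + si)) ** 0.3
        f3 = 1 - 0.25 * oc / (oc + np.exp(3.72 - 2.95 * oc))
        sn1 = 1 - sa / 100
        f4 = 1 - 0.7 * sn1 / (sn1 + np.exp(-5.51 + 22.9 * sn1))
        assert ero.k_factor(sa, si, cl, oc) == pytest.approx(f1 * f2 * f3 * f4, rel=1e-12)

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError):
            ero.k_factor(50.0, 20.0, 10.0, 1.0)


class TestCurveNumber:
    def test_group_ordering_for_forest(self):
        assert ero.curve_number(HSG_A, FOREST) <= ero.curve_number(HSG_D, FOREST)

    def test_lookup_value(self):
        assert ero.curve_number(HSG_A, BARE) == ero.DEFAULT_CN_TABLE[BARE][0]

    def test_full_table_monotone(self):
        for cls, row in ero.DEFAULT_CN_TABLE.items():
            assert list(row) == sorted(row)  # A ≤ B ≤ C ≤ D
            for g in range(4):
                assert ero.DEFAULT_CN_TABLE[FOREST][g] <= ero.DEFAULT_CN_TABLE[BARE][g]

    def test_missing_entry_raises(self):
        with pytest.raises(KeyError):
            ero.curve_number(HSG_A, 99)


class TestScsRunoff:
    def test_below_initial_abstraction(self):
        s = 25400.0 / 80 - 254.0
        assert ero.scs_runoff(0.1 * s, 80.0) == 0.0

    def test_cn_100_passes_everything(self):
        assert ero.scs_runoff(42.0, 100.0) == pytest.approx(42.0)

    def test_hand_value(self):
        # P=100, CN=80 → S=63.5, Q=(100−12.7)²/(100+50.8)
        assert ero.scs_runoff(100.0, 80.0) == pytest.approx(87.3**2 / 150.8, rel=1e-12)

    @pytest.mark.parametrize("cn", [30.0, 55.0, 80.0, 100.0])
    def test_bounded_by_precipitation(self, cn):
        p = np.linspace(0.0, 500.0, 101)
        q = ero.scs_runoff(p, np.full_like(p, cn))
        assert np.all(q >= 0) and np.all(q <= p)

    def test_out_of_range_cn_rejected(self):
        with pytest.raises(ValueError):
            ero.scs_runoff(10.0, 20.0)


class TestRusle:
    def test_unit_factors_return_erosivity(self):
        f = RusleFactors(r=7.0, k=1.0, ls=1.0, c=1.0)
        assert ero.rusle_cell(f) == 7.0

    def test_zero_cover_factor(self):
        f = RusleFactors(r=7.0, k=0.5, ls=2.0, c=0.0)
        assert ero.rusle_cell(f) == 0.0

    def test_product_value(self):
        f = RusleFactors(r=125.59, k=0.3, ls=1.7, c=0.2)
        assert ero.rusle_cell(f) == pytest.approx(125.59 * 0.3 * 1.7 * 0.2)


class TestYield:
    def test_single_hectare_identity(self):
        a = np.array([[5.0]])
        rec = ero.annual_sediment_yield(a, np.array([[True]]), cell_area=1e4, sdr=1.0)
        assert rec.yield_t == pytest.approx(5.0)
        assert rec.yield_t_per_ha == pytest.approx(5.0)

    def test_masked_sum_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 10, (5, 5))
        mask = rng.random((5, 5)) > 0.4
        cell_area = 250.0**2
        rec = ero.annual_sediment_yield(a, mask, cell_area, sdr=0.1)
        expected = 0.1 * a[mask].sum() * cell_area / 1e4
        assert rec.yield_t == pytest.approx(expected, rel=1e-12)
        assert rec.yield_t_per_ha == pytest.approx(expected / (mask.sum() * cell_area / 1e4))

    def test_empty_mask_and_bad_sdr(self):
        a = np.ones((2, 2))
        with pytest.raises(ValueError):
            ero.annual_sediment_yield(a, np.zeros((2, 2), dtype=bool), 1e4)
        with pytest.raises(ValueError):
            ero.annual_sediment_yield(a, np.ones((2, 2), dtype=bool), 1e4, sdr=0.0)


class TestRunAnnual:
    def _inputs(self, stack):
        from reefshed import lulcc, terrain

        fdir = terrain.d8_flow_direction(stack.dem, stack.cell_size)
        acc = terrain.flow_accumulation(fdir)
        lsf = terrain.slope_and_ls(stack.dem, acc, stack.cell_size)
        k = ero.k_factor(stack.sand, stack.silt, stack.clay, stack.org_carbon)
        c = lulcc.to_c_factor(stack.landcover, lulcc.CoverFactorTable())
        masks = {code: terrain.delineate_watershed(fdir, o)
                 for code, o in stack.outlets.items()}
        return k, c, lsf.ls, masks

    def test_zero_precip_zero_yield(self, stack16):
        k, c, ls, masks = self._inputs(stack16)
        recs = ero.run_annual(np.zeros((12, *stack16.shape)), c, k, ls, masks,
                              stack16.cell_area, ero.ErosionConfig())
        assert all(r.yield_t == 0.0 for r in recs.values())

    def test_linear_in_cover_factor(self, stack16, climate10):
        k, c, ls, masks = self._inputs(stack16)
        cfg = ero.ErosionConfig()
        base = ero.run_annual(climate10.precip[0], c, k, ls, masks,
                              stack16.cell_area, cfg)
        double = ero.run_annual(climate10.precip[0], 2 * c, k, ls, masks,
                                stack16.cell_area, cfg)
        for code in masks:
            assert double[code].yield_t == pytest.approx(2 * base[code].yield_t, rel=1e-12)

    def test_precip_scaling_exponent(self, stack16, climate10):
        # P → λP scales MFI by λ and yield by λ^b under R = a·MFI^b
        k, c, ls, masks = self._inputs(stack16)
        cfg = ero.ErosionConfig()
        lam = 1.7
        base = ero.run_annual(climate10.precip[0], c, k, ls, masks,
                              stack16.cell_area, cfg)
        scaled = ero.run_annual(lam * climate10.precip[0], c, k, ls, masks,
                                stack16.cell_area, cfg)
        for code in masks:
            ratio = scaled[code].yield_t / base[code].yield_t
            assert np.log(ratio) / np.log(lam) == pytest.approx(cfg.erosivity.b, rel=1e-9)

    def test_matches_composition_oracle(self, stack16, climate10):
        k, c, ls, masks = self._inputs(stack16)
        cfg = ero.ErosionConfig()
        recs = ero.run_annual(climate10.precip[2], c, k, ls, masks,
                              stack16.cell_area, cfg, year=2003)
        mfi_grid = ero.mfi(climate10.precip[2])
        a_grid = cfg.erosivity.a * mfi_grid**cfg.erosivity.b * k * ls * c
        for code, mask in masks.items():
            expected = cfg.sdr * np.nansum(a_grid[mask]) * stack16.cell_area / 1e4
            assert recs[code].yield_t == pytest.approx(expected, rel=1e-12)

    def test_deforested_cover_yields_more(self, stack16, climate10):
        from reefshed import lulcc

        k, c, ls, masks = self._inputs(stack16)
        table = lulcc.CoverFactorTable()
        surf = lulcc.suitability(np.zeros(stack16.shape), stack16.road_dist,
                                 stack16.landcover, "deforestation")
        lc_def = lulcc.apply_target(stack16.landcover, surf, 1.0)
        c_def = lulcc.to_c_factor(lc_def, table)
        cfg = ero.ErosionConfig()
        base = ero.run_annual(climate10.precip[0], c, k, ls, masks,
                              stack16.cell_area, cfg)
        worse = ero.run_annual(climate10.precip[0], c_def, k, ls, masks,
                               stack16.cell_area, cfg)
        for code in masks:
            assert worse[code].yield_t >= base[code].yield_t
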