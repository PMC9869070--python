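"""Emission terms: equation examples, additivity, linearity, monotonicity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from silagegwp import (
    FermentationProfile,
    ModelConstants,
    analytic_coefficients,
    co2e_total,
    linear_gwp,
    metabolic_co2,
    mgkg_to_percent,
    ozone_co2e,
    percent_to_mgkg,
    printed_coefficients,
    pyruvate_mass_loss,
    respired_co2,
    volatile_mass,
)

# Meta-analysis mean profile in mg/kg (A, E, L, N, D, D_V)
MEAN = dict(acetic=16000.0, ethanol=10000.0, lactic=54000.0, ammonia=2000.0)

conc = st.floats(min_value=0, max_value=2e5, allow_nan=False)


class TestMetabolicCO2:
    def test_zero_metabolites_leave_minor_constant(self):
        assert metabolic_co2(0, 0) == pytest.approx(0.65 * 1.6e3)

    def test_mean_profile(self):
        expected = 0.65 * (16000 * 44.01 / 60.05 + 10000 * 44.01 / 46.07 + 1600)
        assert metabolic_co2(16000, 10000) == pytest.approx(expected)
        assert metabolic_co2(16000, 10000) == pytest.approx(14871, abs=1)

    def test_alternative_grouping_moves_constant_outside(self):
        alt = ModelConstants(hexose_scales_minor_constant=False)
        assert metabolic_co2(0, 0, alt) == pytest.approx(1.6e3)
        # difference between groupings is (1 - 0.65) * 1600 for any inputs
        assert metabolic_co2(7000, 3000, alt) - metabolic_co2(7000, 3000) == (
            pytest.approx(0.35 * 1600))

    @given(a=conc, e=conc, k=st.floats(min_value=0.1, max_value=5))
    def test_variable_part_homogeneous(self, a, e, k):
        base = metabolic_co2(0, 0)
        assert metabolic_co2(k * a, k * e) - base == pytest.approx(
            k * (metabolic_co2(a, e) - base), rel=1e-9, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            metabolic_co2(-1, 0)


class TestOzoneCO2e:
    def test_constants_at_zero_input(self):
        assert ozone_co2e(0, 0, 20) == 6.2e3
        assert ozone_co2e(0, 0, 100) == 1.3e3

    def test_mean_profile_both_horizons(self):
        o3 = 16000 * 0.554 * 0.20 + 10000 * 0.991 * 0.57
        assert ozone_co2e(16000, 10000, 20) == pytest.approx(6200 + 2.04 * o3)
        assert ozone_co2e(16000, 10000, 20) == pytest.approx(21340, abs=1)
        assert ozone_co2e(16000, 10000, 100) == pytest.approx(4343, abs=1)

    def test_unsupported_horizon_rejected(self):
        with pytest.raises(ValueError):
            ozone_co2e(0, 0, 50)


class TestPyruvateLoss:
    def test_minor_constant_only(self):
        assert pyruvate_mass_loss(0, 0, 0) == pytest.approx(0.65 * 3.0 * 99.2)

    def test_mean_profile(self):
        expected = 1.95 * (54000 / 90.08 + 16000 / 60.05 + 10000 / 46.07 + 99.2)
        assert pyruvate_mass_loss(54000, 16000, 10000) == pytest.approx(expected)
        assert pyruvate_mass_loss(54000, 16000, 10000) == pytest.approx(2305, abs=1)

    @given(l=conc, a=conc, e=conc)
    def test_additive_across_metabolites(self, l, a, e):
        base = pyruvate_mass_loss(0, 0, 0)
        parts = (pyruvate_mass_loss(l, 0, 0) + pyruvate_mass_loss(0, a, 0)
                 + pyruvate_mass_loss(0, 0, e) - 2 * base)
        assert pyruvate_mass_loss(l, a, e) == pytest.approx(parts, rel=1e-9)


class TestVolatileMass:
    def test_constant_at_zero(self):
        assert volatile_mass(0, 0, 0, 0) == 6.2e3

    def test_mean_profile(self):
        assert volatile_mass(16000, 10000, 54000, 2000) == pytest.approx(31840)

    @given(a=conc, e=conc, l=conc, n=conc, k=st.floats(min_value=0, max_value=3))
    def test_variable_part_homogeneous(self, a, e, l, n, k):
        base = volatile_mass(0, 0, 0, 0)
        assert volatile_mass(k * a, k * e, k * l, k * n) - base == pytest.approx(
            k * (volatile_mass(a, e, l, n) - base), rel=1e-9, abs=1e-6)


class TestRespiredCO2:
    def test_unit_factor(self):
        assert ModelConstants().respiration_factor == pytest.approx(1.46573, abs=5e-6)

    def test_balance_point_is_zero(self):
        p, c_m = 2000.0, 14000.0
        assert respired_co2(p + c_m + 6200, p, c_m, 6200) == pytest.approx(0)

    def test_vcdml_pathway_mean_profile(self):
        c_m = metabolic_co2(16000, 10000)
        p = pyruvate_mass_loss(54000, 16000, 10000)
        c_r = respired_co2(11000, p, c_m, 6200)
        assert c_r == pytest.approx(-18140, abs=1)


class TestCO2eTotal:
    def test_mean_profile_totals(self):
        prof = FermentationProfile(**MEAN, vcdml=11000)
        bd = co2e_total(prof)
        assert bd.dml_pathway == "vcdml"
        assert bd.gwp20 == pytest.approx(18071, abs=1)
        assert bd.gwp100 == pytest.approx(1074, abs=1)

    @given(a=conc, e=conc, l=conc, dv=st.floats(min_value=-5e4, max_value=2e5))
    def test_additivity_exact(self, a, e, l, dv):
        bd = co2e_total(FermentationProfile(acetic=a, ethanol=e, lactic=l, vcdml=dv))
        assert bd.gwp20 == bd.c_m + bd.c_o20 + bd.c_r
        assert bd.gwp100 == bd.c_m + bd.c_o100 + bd.c_r

    @given(a=conc, e=conc)
    def test_gwp20_exceeds_gwp100(self, a, e):
        bd = co2e_total(FermentationProfile(acetic=a, ethanol=e, lactic=0, vcdml=0))
        assert bd.gwp20 > bd.gwp100

    def test_oven_and_vcdml_pathways_agree(self):
        # C_R via oven DML with full V equals C_R via D_V = D - volatiles
        d = 36000.0
        v = volatile_mass(**{k: MEAN[k] for k in ("acetic", "ethanol", "lactic", "ammonia")})
        dv = d - (0.554 * MEAN["acetic"] + 0.991 * MEAN["ethanol"]
                  + 1.003 * MEAN["ammonia"] + 0.090 * MEAN["lactic"])
        oven = co2e_total(FermentationProfile(**MEAN, dml=d), prefer="oven")
        vc = co2e_total(FermentationProfile(**MEAN, vcdml=dv))
        assert oven.c_r == pytest.approx(vc.c_r, rel=1e-12)
        assert oven.gwp20 == pytest.approx(vc.gwp20, rel=1e-12)

    def test_missing_dml_rejected(self):
        with pytest.raises(ValueError):
            co2e_total(FermentationProfile(acetic=1, ethanol=1, lactic=1))

    def test_monotonicity_signs(self):
        # dGWP/dDV > 0, dGWP20/dE > 0, dGWP/dL < 0, dGWP/dA < 0 on both horizons
        base = FermentationProfile(**MEAN, vcdml=11000)
        b0 = co2e_total(base)
        up = lambda **kw: co2e_total(FermentationProfile(**{**MEAN, "vcdml": 11000, **kw}))
        assert up(vcdml=12000).gwp20 > b0.gwp20
        assert up(vcdml=12000).gwp100 > b0.gwp100
        assert up(ethanol=11000).gwp20 > b0.gwp20
        assert up(lactic=55000).gwp20 < b0.gwp20
        assert up(lactic=55000).gwp100 < b0.gwp100
        assert up(acetic=17000).gwp20 < b0.gwp20
        assert up(acetic=17000).gwp100 < b0.gwp100


class TestLinearGWP:
    def test_all_zero_profile_returns_intercept(self):
        c = printed_coefficients(20)
        assert linear_gwp(0, 0, 0, 0, c) == c.intercept

    def test_mean_profile_printed_coefficients(self):
        val = linear_gwp(16000, 10000, 54000, 11000, printed_coefficients(20))
        assert val == pytest.approx(18100, abs=100)

    def test_dv_slope_equals_respiration_factor(self):
        assert printed_coefficients(20).slope_dv == pytest.approx(
            6 * 44.01 / 180.156, abs=5e-6)

    def test_missing_vcdml_rejected(self):
        with pytest.raises(ValueError):
            linear_gwp(1, 1, 1, None, printed_coefficients(20))

    def test_full_equation_matches_analytic_surrogate_pointwise(self):
        rng = np.random.default_rng(7)
        a, e, l = rng.uniform(0, 5e4, (3, 200))
        dv = rng.uniform(-3e4, 8e4, 200)
        for h in (20, 100):
            coef = analytic_coefficients(horizon=h)
            lin = linear_gwp(a, e, l, dv, coef)
            full = [co2e_total(FermentationProfile(
                acetic=ai, ethanol=ei, lactic=li, vcdml=di)).__getattribute__(f"gwp{h}")
                for ai, ei, li, di in zip(a, e, l, dv)]
            assert np.max(np.abs(np.asarray(full) - lin)) < 1e-6


class TestUnits:
    @pytest.mark.parametrize("pct,mg", [(1.6, 16000), (0.0, 0.0), (0.2, 2000)])
    def test_percent_conversion(self, pct, mg):
        assert percent_to_mgkg(pct) == mg

    @given(x=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_round_trip(self, x):
        assert mgkg_to_percent(percent_to_mgkg(x)) == pytest.approx(x, rel=1e-12, abs=1e-12)
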