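"""Calorespirometric ratio, saturation fits, growth, biomass and photon budget."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import photocr as p
from photocr.derived import BiomassModel, SaturationFit


class TestCalorespirometricRatio:
    def test_exact_linear_pair(self):
        r = np.linspace(1e-10, 8e-10, 40)
        out = p.calorespirometric_ratio(455e3 * r, r)
        assert out.ratio_kj_per_mol == pytest.approx(-455.0, rel=1e-12)
        assert out.pearson_r == pytest.approx(1.0)

    def test_shuffled_pairing_destroys_correlation(self):
        rng = np.random.default_rng(5)
        r = np.linspace(1e-10, 8e-10, 200)
        pps = 455e3 * r + rng.normal(0, 1e-6, r.size)
        out = p.calorespirometric_ratio(pps, rng.permutation(r))
        assert abs(out.pearson_r) < 0.3

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            p.calorespirometric_ratio(np.ones(20), np.full(20, 1e-10))
        with pytest.raises(ValueError, match="10"):
            p.calorespirometric_ratio(np.arange(5.0), np.arange(5.0))


class TestOxycaloricScaling:
    def test_unit_arithmetic(self):
        assert p.scale_oxygen_to_power(1e-6, -455.0) == pytest.approx(0.455)
        assert p.scale_oxygen_to_power(0.0) == 0.0

    def test_specific_vmax_scaling(self):
        # |oxycal| * v_max,O2: 455e3 * 2.95e-6 = 1.342 W/g
        assert p.scale_oxygen_to_power(2.95e-6, -455.0) == pytest.approx(1.342, abs=1e-3)


class TestSaturationFit:
    VMAX, KM = 1.61, 42.6e-3

    def _v(self, p_i):
        return self.VMAX * p_i / (self.KM + p_i)

    def test_exact_recovery(self):
        p_i = np.linspace(1e-3, 0.1058, 30)
        fit = p.fit_saturation(p_i, self._v(p_i))
        assert fit.v_max == pytest.approx(self.VMAX, rel=1e-7)
        assert fit.k_m_W == pytest.approx(self.KM, rel=1e-7)

    def test_half_saturation_identity(self):
        fit = SaturationFit(self.VMAX, self.KM, 0.0, 0.0, 0)
        assert fit.predict(self.KM) == pytest.approx(self.VMAX / 2)

    def test_monte_carlo_with_noise(self):
        p_i = np.linspace(0, 0.1058, 31)[1:]
        ok_v, ok_k = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            v = self._v(p_i) * (1 + 0.02 * rng.normal(size=p_i.size))
            fit = p.fit_saturation(p_i, v)
            ok_v.append(abs(fit.v_max - self.VMAX) / self.VMAX < 0.03)
            ok_k.append(abs(fit.k_m_W - self.KM) / self.KM < 0.07)
        assert np.mean(ok_v) >= 0.9 and np.mean(ok_k) >= 0.9

    def test_low_light_linear_limit(self):
        # for P_I << k_m the initial slope approaches v_max/k_m
        p_i = np.linspace(1e-5, 0.002, 50)
        slope = np.polyfit(p_i, self._v(p_i), 1)[0]
        assert slope == pytest.approx(self.VMAX / self.KM, rel=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            p.fit_saturation([0.01, 0.02], [0.3, 0.5])


class TestRatioOfVmax:
    def test_printed_values(self):
        fe = SaturationFit(1.61, 42.6e-3, 0.02, 1.4e-3, 30)
        fo = SaturationFit(2.95e-6, 47.4e-3, 0.07e-6, 2.5e-3, 30)
        val, se = p.ratio_of_vmax(fe, fo)
        assert val == pytest.approx(-545.8, abs=0.3)
        assert se > 0

    def test_scale_invariance(self):
        fe = SaturationFit(1.61, 42.6e-3, 0.02, 0.0, 0)
        fo = SaturationFit(2.95e-6, 42.6e-3, 0.07e-6, 0.0, 0)
        v1, _ = p.ratio_of_vmax(fe, fo)
        fe2 = SaturationFit(fe.v_max * 7, fe.k_m_W, fe.v_max_se * 7, 0.0, 0)
        fo2 = SaturationFit(fo.v_max * 7, fo.k_m_W, fo.v_max_se * 7, 0.0, 0)
        v2, _ = p.ratio_of_vmax(fe2, fo2)
        assert v2 == pytest.approx(v1, rel=1e-12)

    def test_propagated_se_matches_sampling(self):
        fe = SaturationFit(1.61, 42.6e-3, 0.02, 0.0, 0)
        fo = SaturationFit(2.95e-6, 47.4e-3, 0.07e-6, 0.0, 0)
        _, se = p.ratio_of_vmax(fe, fo)
        rng = np.random.default_rng(6)
        draws = -(rng.normal(fe.v_max, fe.v_max_se, 20000)
                  / rng.normal(fo.v_max, fo.v_max_se, 20000)) / 1e3
        assert se == pytest.approx(draws.std(), rel=0.1)


class TestGrowthRate:
    def test_e_fold(self):
        est = p.growth_rate(1.0, np.e, 1.0)
        assert est.mu_per_h == pytest.approx(1.0)

    def test_no_growth(self):
        assert p.growth_rate(2.0, 2.0, 5.0).mu_per_h == 0.0

    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=0.1, max_value=10.0),
           st.floats(min_value=0.01, max_value=24.0))
    def test_scale_invariance(self, scale, ratio, dt):
        a = p.growth_rate(1.0, ratio, dt).mu_per_h
        b = p.growth_rate(scale, scale * ratio, dt).mu_per_h
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            p.growth_rate(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            p.growth_rate(1.0, 1.0, 0.0)


class TestPpsVsCells:
    SLOPE = 3.09e-4  # uW mL per cell

    def test_exact_line_through_origin(self):
        cn = np.array([1e5, 3e5, 5e5, 7.39e5, 1e6])
        fit = p.pps_vs_cells(cn, self.SLOPE * cn)
        assert fit.slope == pytest.approx(self.SLOPE, rel=1e-12)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_relative_slope_error_arithmetic(self):
        # 0.13/3.09 is the ~4.2% relative PE error of the cell-number fit
        assert 100 * 0.13e-4 / self.SLOPE == pytest.approx(4.2, abs=0.1)

    def test_fit_se_matches_analytic_ols(self):
        cn = np.linspace(1e5, 1e6, 12)
        sigma = 20.0
        ses = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = p.pps_vs_cells(cn, self.SLOPE * cn + rng.normal(0, sigma, cn.size))
            ses.append(fit.slope_se)
        analytic = sigma / np.sqrt(np.sum((cn - cn.mean()) ** 2))
        assert np.mean(ses) == pytest.approx(analytic, rel=0.15)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            p.pps_vs_cells([1e5, 1e5], [1.0, 1.0])


class TestCellScalars:
    def test_cell_specific_power(self):
        val, se = p.cell_specific_power(3.09e-4, v_l_mL=10.0, slope_se=0.13e-4)
        assert val == pytest.approx(30.9, abs=0.05)
        assert se == pytest.approx(1.3, abs=0.05)
        val2, _ = p.cell_specific_power(2 * 3.09e-4, v_l_mL=10.0)
        assert val2 == pytest.approx(2 * val)

    def test_cell_dry_mass(self):
        pg, se = p.cell_dry_mass(BiomassModel())
        assert pg == pytest.approx(52.5, abs=0.1)
        # first-order propagation of the two conversion-slope errors
        assert se == pytest.approx(2.5, abs=0.2)
        pg2, _ = p.cell_dry_mass(BiomassModel(
            cdw_per_od_g_per_l=1.0, cdw_per_od_se=0.0,
            cells_per_od_per_ml=1e9, cells_per_od_se=0.0))
        assert pg2 == pytest.approx(1.0)


class TestMolarMass:
    def test_mean_biomass_composition(self):
        assert p.biomass_molar_mass("CH1.821O0.605N0.103") == pytest.approx(24.97, abs=0.01)

    @pytest.mark.parametrize("formula, mass", [("C", 12.011), ("CH4", 16.043)])
    def test_simple_formulas(self, formula, mass):
        assert p.biomass_molar_mass(formula) == pytest.approx(mass, abs=1e-3)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            p.biomass_molar_mass("CXy2")


class TestPhotonBudget:
    MM = p.biomass_molar_mass("CH1.821O0.605N0.103")

    def test_worked_numbers(self):
        budget = p.photon_budget(0.074, 0.40, 0.079, 3.88e-4, self.MM)
        assert budget.photons_per_co2 == pytest.approx(86.8, abs=0.3)
        assert budget.g_per_einstein == pytest.approx(0.29, abs=0.005)
        assert not budget.below_theoretical_floor

    @given(st.floats(min_value=0.01, max_value=10.0),
           st.floats(min_value=0.05, max_value=1.0),
           st.floats(min_value=0.005, max_value=0.5),
           st.floats(min_value=1e-5, max_value=1e-2))
    def test_algebraic_identity(self, flow, frac, mu, x0):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            budget = p.photon_budget(flow, frac, mu, x0, self.MM)
        assert budget.photons_per_co2 * budget.g_per_einstein == pytest.approx(
            self.MM, rel=1e-9)

    def test_below_quantum_floor_warns(self):
        with pytest.warns(UserWarning, match="8 photons"):
            budget = p.photon_budget(0.074, 0.40, 10.0, 3.88e-4, self.MM)
        assert budget.below_theoretical_floor


class TestReactionRatio:
    def test_glucose_photosynthesis(self):
        assert p.reaction_ratio(2813.6, 6) == pytest.approx(-469, abs=0.2)

    def test_one_mehler_event_per_photosynthesis(self):
        # (2813.6 + 91) kJ over a net 5 mol O2
        val = p.reaction_ratio(2813.6, 6, delta_h_side_kj_per_mol=91.0,
                               n_o2_side=1, side_per_photo=1.0)
        assert val == pytest.approx(-580.9, abs=0.1)

    def test_no_side_reaction_reduces_to_pure(self):
        pure = p.reaction_ratio(2813.6, 6)
        assert p.reaction_ratio(2813.6, 6, 91.0, 1, 0.0) == pytest.approx(pure)

    def test_zero_net_oxygen_rejected(self):
        with pytest.raises(ValueError):
            p.reaction_ratio(2813.6, 6, 91.0, 6, 1.0)
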