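"""Virtual-instrument invariants: closures, determinism, scenario shapes."""

import numpy as np
import pytest

import photocr as p
from photocr.gas_exchange import XI_AIR, OxygenTrace
from photocr.simulate import carbon_limited_scenario


class TestDeterminism:
    def test_identical_seed_identical_channels(self, short_program, cal):
        cfg = p.SimulationConfig(program=short_program, calibration=cal)
        a = p.simulate_run(cfg, seed=7)
        b = p.simulate_run(cfg, seed=7)
        for ch in ("dp_heat_uW", "o2_liquid_pct", "o2_gas_pct", "led_current_mA"):
            assert np.array_equal(getattr(a.live, ch), getattr(b.live, ch))
            assert np.array_equal(getattr(a.dead, ch), getattr(b.dead, ch))

    def test_different_seed_different_noise(self, short_program, cal):
        cfg = p.SimulationConfig(program=short_program, calibration=cal)
        a = p.simulate_run(cfg, seed=7)
        b = p.simulate_run(cfg, seed=8)
        assert not np.array_equal(a.live.dp_heat_uW, b.live.dp_heat_uW)


class TestEnergyClosure:
    def test_instantaneous_balance(self, quiet_run):
        t = quiet_run.truth
        np.testing.assert_allclose(t.p_i_W - t.p_heat_m_W - t.p_ps_W, 0.0, atol=1e-16)

    def test_differential_channels_encode_pps(self, quiet_run):
        # noise-free: live minus dead differential equals the true P_PS
        diff = (quiet_run.live.dp_heat_uW - quiet_run.dead.dp_heat_uW) * 1e-6
        np.testing.assert_allclose(diff, quiet_run.truth.p_ps_W, atol=1e-15)

    def test_pps_slaved_to_oxygen(self, quiet_run):
        cfg = quiet_run.config
        expected = abs(cfg.oxycal_kj_per_mol) * 1e3 * quiet_run.truth.R_o2_mol_per_s
        np.testing.assert_allclose(quiet_run.truth.p_ps_W, expected, rtol=1e-12)


class TestOxygenClosure:
    def test_moles_balance_integrated_production(self, quiet_run):
        cfg = quiet_run.config
        total = quiet_run.truth.total_o2_mol(cfg)
        drift = total - total[0] - quiet_run.truth.cum_o2_mol
        assert np.max(np.abs(drift)) < 1e-9 * total[0]

    def test_abiotic_run_conserves_moles(self, short_program, cal):
        cfg = p.SimulationConfig(program=short_program, calibration=cal,
                                 v_max_mol_g_s=0.0, mu_per_h=0.0,
                                 sigma_heat_W=0.0, sigma_o2_pct=0.0)
        run = p.simulate_run(cfg, seed=0)
        total = run.truth.total_o2_mol(cfg)
        np.testing.assert_allclose(total, total[0], rtol=1e-12)
        ox = OxygenTrace.from_instrument(run.live)
        rates = p.production_rate(ox, cfg.k_v_per_s)
        assert np.max(np.abs(rates.r_o2_mol_per_l_s)) < 1e-15


class TestClosedLoopReduction:
    def test_noise_free_pe_matches_truth(self, quiet_run):
        res = p.reduce_run(quiet_run.live, quiet_run.dead, quiet_run.config.calibration)
        m = np.isfinite(res.pe)
        rel = np.abs(res.pe[m] - quiet_run.truth.pe[m]) / quiet_run.truth.pe[m]
        assert np.max(rel) < 1e-6

    def test_configured_pe_recovered_at_low_light(self, short_program, cal):
        # choose v_max so the plateau PE is 0.03, then recover it
        pe_target = 0.03
        p_max = short_program.p_max_W(cal)
        k_m = 47.4e-3
        v_max = pe_target * (k_m + p_max) / (455e3 * 3.88e-4)
        cfg = p.SimulationConfig(program=short_program, calibration=cal,
                                 mu_per_h=0.0, v_max_mol_g_s=v_max, k_m_W=k_m)
        run = p.simulate_run(cfg, seed=2)
        res = p.reduce_run(run.live, run.dead, cal)
        lo, hi = short_program.plateau_window(0)
        m = (res.time_s >= lo) & (res.time_s < hi)
        assert np.nanmean(res.pe[m]) == pytest.approx(pe_target, rel=0.10)

    def test_pe_never_exceeds_quantum_ceiling(self, noisy_run):
        cfg = noisy_run.config
        res = p.reduce_run(noisy_run.live, noisy_run.dead, cfg.calibration)
        lo, hi = cfg.program.plateau_window(cfg.program.n_ramps - 1)
        m = (res.time_s >= lo) & (res.time_s < hi)
        pe_true = np.nanmean(noisy_run.truth.pe[m])
        noise_rel = np.sqrt(2) * cfg.sigma_heat_W / np.sqrt(m.sum()) / (
            cfg.program.p_max_W(cfg.calibration) * pe_true)
        assert np.nanmean(res.pe[m]) <= pe_true * (1 + 5 * noise_rel)


class TestLinearity:
    def test_doubling_biomass_doubles_pps(self, short_program, cal):
        base = p.SimulationConfig(program=short_program, calibration=cal,
                                  mu_per_h=0.0, sigma_heat_W=0.0, sigma_o2_pct=0.0)
        double = p.SimulationConfig(program=short_program, calibration=cal,
                                    mu_per_h=0.0, x0_g=2 * base.x0_g,
                                    sigma_heat_W=0.0, sigma_o2_pct=0.0)
        a = p.simulate_run(base, seed=0).truth
        b = p.simulate_run(double, seed=0).truth
        lo, hi = short_program.plateau_window(0)
        m = (a.time_s >= lo) & (a.time_s < hi)
        assert b.p_ps_W[m].mean() == pytest.approx(2 * a.p_ps_W[m].mean(), rel=1e-9)


class TestCarbonLimitation:
    def test_pre_plateau_maximum_in_first_ramp(self, cal):
        cfg = carbon_limited_scenario(calibration=cal)
        run = p.simulate_run(cfg, seed=0)
        truth = run.truth
        lo, hi = cfg.program.ramp_window(0)
        _, plateau_end = cfg.program.plateau_window(0)
        m = (truth.time_s >= lo) & (truth.time_s < hi)
        t_max = truth.time_s[m][np.argmax(truth.p_ps_W[m])]
        assert t_max < plateau_end

    def test_declining_ramp_maxima(self, cal):
        cfg = carbon_limited_scenario(calibration=cal)
        truth = p.simulate_run(cfg, seed=0).truth
        maxima = []
        for i in range(cfg.program.n_ramps):
            lo, hi = cfg.program.ramp_window(i)
            m = (truth.time_s >= lo) & (truth.time_s < hi)
            maxima.append(truth.p_ps_W[m].max())
        assert maxima[0] > maxima[1] > maxima[2]


class TestExchangeOnly:
    def test_approaches_equilibrium(self, quiet_config):
        trace = p.simulate_exchange_only(quiet_config, duration_s=6 * 3600.0)
        eq = quiet_config.k_h * trace.xi_o[-1] * quiet_config.pressure_pa
        assert trace.o_l_mol_per_l[-1] == pytest.approx(eq, rel=1e-3)

    def test_matches_analytic_two_compartment_solution(self, quiet_config):
        from scipy import constants as const
        cfg = quiet_config
        trace = p.simulate_exchange_only(cfg, duration_s=7200.0)
        # the driving force decays with the effective rate of the coupled pair
        alpha = cfg.k_h * const.R * cfg.temp_K * cfg.v_l_L / (cfg.v_g_L * 1e-3)
        k_eff = cfg.k_v_per_s * (1.0 + alpha)
        d0 = trace.o_l_mol_per_l[0] - cfg.k_h * trace.xi_o[0] * cfg.pressure_pa
        drive = trace.o_l_mol_per_l - cfg.k_h * trace.xi_o * cfg.pressure_pa
        np.testing.assert_allclose(drive, d0 * np.exp(-k_eff * trace.time_s),
                                   rtol=1e-6, atol=1e-12)

    def test_mole_conservation_between_phases(self, quiet_config):
        from scipy import constants as const
        cfg = quiet_config
        trace = p.simulate_exchange_only(cfg, duration_s=3600.0)
        gas = trace.xi_o * cfg.pressure_pa * (cfg.v_g_L * 1e-3) / (const.R * cfg.temp_K)
        total = trace.o_l_mol_per_l * cfg.v_l_L + gas
        np.testing.assert_allclose(total, total[0], rtol=1e-9)


class TestReplicateBatch:
    def test_single_replicate_equals_run(self, quiet_config):
        batch = p.replicate_batch(quiet_config, 1, base_seed=3)
        run = p.simulate_run(quiet_config, seed=3)
        assert np.array_equal(batch[0].live.dp_heat_uW, run.live.dp_heat_uW)

    def test_duplicate_seeds_warn(self, quiet_config):
        with pytest.warns(UserWarning, match="duplicate"):
            p.replicate_batch(quiet_config, 2, seeds=[5, 5])

    def test_pooled_sd_within_chi2_band(self, short_program, cal):
        cfg = p.SimulationConfig(program=short_program, calibration=cal)
        runs = p.replicate_batch(cfg, 8, base_seed=20)
        traces = [p.HeatTrace(r.dead.time_s, r.dead.dp_heat_uW * 1e-6, "dead",
                              short_program) for r in runs]
        st = p.plateau_statistics(traces, p_max_W=short_program.p_max_W(cal))
        n = st.n
        # two-sided 99% chi-square band for the SD of n pooled samples
        from scipy.stats import chi2
        lo = np.sqrt(chi2.ppf(0.005, n - 1) / (n - 1))
        hi = np.sqrt(chi2.ppf(0.995, n - 1) / (n - 1))
        assert lo <= st.sd_W / cfg.sigma_heat_W <= hi


class TestValidation:
    def test_bad_config_rejected(self, short_program, cal):
        with pytest.raises(ValueError):
            p.SimulationConfig(program=short_program, calibration=cal, x0_g=0.0)
        with pytest.raises(ValueError):
            p.SimulationConfig(program=short_program, calibration=cal, c0_mol_l=-1.0)
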