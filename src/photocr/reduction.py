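"""End-to-end reduction: paired raw runs -> PE, r_O2 and derived scalars."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import derived, energy, gas_exchange
from .io import InstrumentTrace, config_hash
from .optics import CalibrationModel, LightProgram


@dataclass
class ReductionOptions:
    baseline_window_s: float = 600.0
    pe_threshold_frac: float = 0.05
    smooth_window_s: float = 301.0
    polyorder: int = 2
    sign: int = +1
    k_v_per_s: float | None = None     # fall back to the run metadata
    k_h: float = gas_exchange.HENRY_DEFAULT
    pressure_pa: float = gas_exchange.PRESSURE_DEFAULT
    v_l_L: float = 0.010
    v_g_L: float = 0.010
    temp_K: float = 293.15
    gas_units: str = "percent_volume"
    biomass_g: float | None = None     # fall back to the run metadata
    ramp_smooth_s: float = 300.0


@dataclass
class ReductionResult:
    time_s: np.ndarray
    p_i_W: np.ndarray
    p_ps_W: np.ndarray
    pe: np.ndarray
    r_o2_mol_per_l_s: np.ndarray | None
    R_o2_mol_per_s: np.ndarray | None
    caloresp: derived.CalorespROutput | None
    sat_energy: derived.SaturationFit | None
    sat_oxygen: derived.SaturationFit | None
    growth: derived.GrowthEstimate | None
    program: LightProgram
    report: dict = field(default_factory=dict)

    def series_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.time_s,
            "p_i_W": self.p_i_W,
            "p_ps_W": self.p_ps_W,
            "pe": self.pe,
        })
        if self.r_o2_mol_per_l_s is not None:
            df["r_o2_mol_per_l_s"] = self.r_o2_mol_per_l_s
            df["R_o2_mol_per_s"] = self.R_o2_mol_per_s
        return df


def _meta_float(meta: dict, key: str) -> float | None:
    try:
        return float(meta[key])
    except (KeyError, TypeError, ValueError):
        return None


def _report_entry(value, se=None, units="", definition=""):
    return {"value": value, "se": se, "units": units, "definition": definition}


def reduce_run(
    live: InstrumentTrace,
    dead: InstrumentTrace,
    calibration: CalibrationModel,
    program: LightProgram | None = None,
    options: ReductionOptions | None = None,
) -> ReductionResult:
    """Run the full chain on a paired live/dead run.

    Steps: baseline-correct both differential heat traces on the dark
    lead-in, align on the light-program clock (onset detected from the LED
    current channel), form ``P_PS = ΔP_live − ΔP_dead`` and ``PE = P_PS/P_I``
    (masked at low light), reconstruct the gas-exchange-corrected ``r_O2``
    from the optode channels, then fit the calorespirometric ratio, the
    saturation curves of both observables and — for repeated-ramp programs —
    the specific growth rate.
    """
    opt = options or ReductionOptions()
    program = program or LightProgram.from_meta(live.meta)
    if program is None:
        raise ValueError("no light program: pass one or use run files with program metadata")
    prog_dead = LightProgram.from_meta(dead.meta)
    if prog_dead is not None and not program.matches(prog_dead):
        raise ValueError("live and dead runs were recorded under different light programs")

    def _heat(trace: InstrumentTrace, role: str) -> energy.HeatTrace:
        t = _align_to_program(trace, program)
        ht = energy.HeatTrace(
            time_s=t, power_W=opt.sign * trace.dp_heat_uW * 1e-6,
            role=role, program=program,
        )
        window = min(opt.baseline_window_s, program.lead_in_s)
        return energy.baseline_correct(ht, window) if window > 0 else ht

    live_h = _heat(live, "live")
    dead_h = _heat(dead, "dead")
    time_s, p_ps = energy.conserved_power(live_h, dead_h)
    p_i = np.asarray(calibration.power_W(live.led_current_mA, check_range=False))
    pe = energy.compute_pe(p_ps, p_i, threshold_frac=opt.pe_threshold_frac)

    # oxygen branch
    k_v = opt.k_v_per_s if opt.k_v_per_s is not None else _meta_float(live.meta, "k_v_per_s")
    r_o2 = R_o2 = None
    caloresp = None
    if k_v is not None:
        ox = gas_exchange.OxygenTrace.from_instrument(
            live, k_h=opt.k_h, pressure_pa=opt.pressure_pa,
            v_l_L=opt.v_l_L, v_g_L=opt.v_g_L, temp_K=opt.temp_K,
            gas_units=live.meta.get("o2_gas_units", opt.gas_units),
        )
        rates = gas_exchange.production_rate(ox, k_v, opt.smooth_window_s, opt.polyorder)
        r_o2, R_o2 = rates.r_o2_mol_per_l_s, rates.R_o2_mol_per_s
        mask = np.isfinite(pe)
        try:
            caloresp = derived.calorespirometric_ratio(p_ps[mask], R_o2[mask])
        except ValueError:
            caloresp = None

    # saturation fits need a biomass reference
    biomass = opt.biomass_g if opt.biomass_g is not None else _meta_float(live.meta, "x0_g")
    sat_e = sat_o = None
    if biomass:
        mask = np.isfinite(pe)
        try:
            sat_e = derived.fit_saturation(p_i[mask], p_ps[mask] / biomass)
        except (ValueError, RuntimeError):
            sat_e = None
        if R_o2 is not None:
            try:
                sat_o = derived.fit_saturation(p_i[mask], R_o2[mask] / biomass)
            except (ValueError, RuntimeError):
                sat_o = None

    growth = None
    if program.n_ramps >= 2:
        try:
            growth = derived.growth_rate_from_ramps(
                time_s, p_ps, program, smooth_s=opt.ramp_smooth_s, source="heat"
            )
        except ValueError:
            growth = None

    report = _build_report(
        program, calibration, time_s, pe, p_i, caloresp, sat_e, sat_o, growth, opt
    )
    return ReductionResult(
        time_s=time_s, p_i_W=p_i, p_ps_W=p_ps, pe=pe,
        r_o2_mol_per_l_s=r_o2, R_o2_mol_per_s=R_o2,
        caloresp=caloresp, sat_energy=sat_e, sat_oxygen=sat_o,
        growth=growth, program=program, report=report,
    )


def _align_to_program(trace: InstrumentTrace, program: LightProgram) -> np.ndarray:
    """Shift the time axis so light onset sits at the program lead-in.

    Onset is detected from the logged LED current channel (not from heat, to
    avoid circularity).  Traces already on the program clock are returned
    unchanged.
    """
    cur = trace.led_current_mA
    thresh = 1e-3 * max(float(np.max(cur)), 1e-9)
    on = np.nonzero(cur > thresh)[0]
    if on.size == 0:
        return trace.time_s
    # light onset = last dark sample before the current first rises
    t_on = trace.time_s[max(on[0] - 1, 0)]
    return trace.time_s - t_on + program.lead_in_s


def _build_report(program, calibration, time_s, pe, p_i, caloresp, sat_e, sat_o, growth,
                  opt: ReductionOptions) -> dict:
    rep = {
        "config_hash": config_hash({
            "program": program.to_meta(), "calibration": calibration.to_dict(),
            "options": asdict(opt),
        }),
        "p_i_max_W": _report_entry(float(np.max(p_i)), units="W",
                                   definition="P_I^Max = Phi(I_max)*N_A*E_P"),
    }
    for i in range(program.n_ramps):
        lo, hi = program.plateau_window(i)
        mask = (time_s >= lo) & (time_s < hi)
        if mask.any():
            rep[f"pe_plateau_mean_R{i + 1}"] = _report_entry(
                float(np.nanmean(pe[mask])), units="-", definition="PE = P_PS/P_I",
            )
    if caloresp is not None:
        rep["caloresp_ratio"] = _report_entry(
            caloresp.ratio_kj_per_mol, caloresp.se_kj_per_mol, "kJ/mol O2",
            "-slope of OLS P_PS vs R_O2",
        )
        rep["caloresp_pearson_r"] = _report_entry(caloresp.pearson_r, units="-")
    if sat_e is not None:
        rep["v_max_energy"] = _report_entry(sat_e.v_max, sat_e.v_max_se, "W/g",
                                            "v = v_max*P_I/(k_m+P_I)")
        rep["k_m_energy"] = _report_entry(sat_e.k_m_W, sat_e.k_m_se, "W")
    if sat_o is not None:
        rep["v_max_oxygen"] = _report_entry(sat_o.v_max, sat_o.v_max_se, "mol/g/s",
                                            "v = v_max*P_I/(k_m+P_I)")
        rep["k_m_oxygen"] = _report_entry(sat_o.k_m_W, sat_o.k_m_se, "W")
        if sat_e is not None:
            try:
                val, se = derived.ratio_of_vmax(sat_e, sat_o)
                rep["oxycal_from_vmax"] = _report_entry(val, se, "kJ/mol O2",
                                                        "-(v_max_E/v_max_O2)")
            except ValueError:
                pass
    if growth is not None:
        rep["mu"] = _report_entry(growth.mu_per_h, units="1/h",
                                  definition="mu = ln(Xn/X1)/dt from ramp maxima")
    return rep


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a report dict into a key/value/SE/units table."""
    rows = []
    for key, entry in report.items():
        if isinstance(entry, dict):
            rows.append({
                "key": key, "value": entry.get("value"), "se": entry.get("se"),
                "units": entry.get("units", ""), "definition": entry.get("definition", ""),
            })
        else:
            rows.append({"key": key, "value": entry, "se": None, "units": "", "definition": ""})
    return pd.DataFrame(rows)
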