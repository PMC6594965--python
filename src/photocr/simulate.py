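"""Virtual photocalorespirometer.

Generates paired live/dead raw runs with known ground truth so every
reduction stage can be closed-loop tested without hardware.  The forward
model is intentionally the same physics the reduction inverts:

* incident power P_I(t) from the trapezoidal current program through the
  optics calibration;
* biomass X(t) growing exponentially at the configured µ while the light is
  on (growth is prescribed, not emergent, to keep the ground truth simple);
* specific O2 production following a Michaelis–Menten-like light response
  ``v_max·P_I/(k_m + P_I)``, optionally throttled by a lumped dissolved
  carbon pool ``C/(K_C + C)``;
* conserved energy slaved to the O2 rate through a single true oxycaloric
  equivalent: ``P_PS = |oxycal|·r_O2·V_L`` at all times;
* first-order liquid<->headspace O2 exchange at k_V with an isobaric,
  ideal-gas headspace balance;
* Gaussian heat-flow noise (default SD 25 µW) and multiplicative optode
  noise; channels written at 1 Hz.

The differential heat channels follow the convention that live minus dead
equals +P_PS: dead = imbalance·P_I + noise, live = imbalance·P_I + P_PS +
noise, where ``arm_imbalance`` models the slight asymmetry of the two-arm
light guide.

Integration is fixed-step classical Runge–Kutta on the 1 s instrument clock
(the dynamics, rates ≲ 1e-3 s⁻¹, are far from stiff).  RK4 preserves linear
invariants, so total O2 moles minus the integrated production are conserved
to machine precision — the basis of the mole-conservation tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import constants as const

from .gas_exchange import HENRY_DEFAULT, PRESSURE_DEFAULT, XI_AIR, OxygenTrace
from .io import InstrumentTrace, config_hash
from .optics import CalibrationModel, LightProgram, default_calibration


class SimulationError(RuntimeError):
    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass
class SimulationConfig:
    """Ground-truth physiological and instrument parameters of a run."""

    program: LightProgram = field(default_factory=LightProgram)
    calibration: CalibrationModel = field(default_factory=default_calibration)
    # physiology
    mu_per_h: float = 0.071
    x0_g: float = 3.88e-4              # 7.39e5 cells/mL * 52.5 pg * 10 mL
    cn0_per_ml: float = 7.39e5
    oxycal_kj_per_mol: float = -455.0
    v_max_mol_g_s: float = 2.95e-6     # specific O2 rate amplitude
    k_m_W: float = 47.4e-3             # half-saturation incident power
    dark_respiration_mol_g_s: float = 0.0
    # carbon pool (None -> no limitation)
    c0_mol_l: float | None = None
    k_c_mol_l: float = 0.5e-3
    # vessel / exchange
    k_v_per_s: float = 1.150e-3
    k_h: float = HENRY_DEFAULT
    pressure_pa: float = PRESSURE_DEFAULT
    v_l_L: float = 0.010
    v_g_L: float = 0.010
    temp_K: float = 293.15
    # instrument
    sigma_heat_W: float = 25e-6
    sigma_o2_pct: float = 0.1          # % of reading, multiplicative
    arm_imbalance: float = 0.03
    o2_gas_units: str = "percent_volume"

    def __post_init__(self):
        if min(self.x0_g, self.v_l_L, self.v_g_L, self.temp_K, self.pressure_pa) <= 0:
            raise ValueError("volumes, biomass, temperature and pressure must be positive")
        if self.k_v_per_s < 0 or self.v_max_mol_g_s < 0 or self.k_m_W < 0:
            raise ValueError("rates must be non-negative")
        if self.sigma_heat_W < 0 or self.sigma_o2_pct < 0:
            raise ValueError("noise levels must be non-negative")
        if self.c0_mol_l is not None and self.c0_mol_l <= 0:
            raise ValueError("carbon pool must be positive when enabled")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        return config_hash(self.to_dict())


@dataclass
class GroundTruth:
    """Noise-free state and derived series of a simulated run."""

    time_s: np.ndarray
    p_i_W: np.ndarray
    p_ps_W: np.ndarray
    r_o2_mol_per_l_s: np.ndarray
    R_o2_mol_per_s: np.ndarray
    x_g: np.ndarray
    c_mol_l: np.ndarray | None
    o_l_mol_per_l: np.ndarray
    xi_o: np.ndarray
    pe: np.ndarray
    cum_o2_mol: np.ndarray

    @property
    def p_heat_m_W(self) -> np.ndarray:
        """Absolute M-side heat flow implied by the energy balance."""
        return self.p_i_W - self.p_ps_W

    def total_o2_mol(self, cfg: SimulationConfig) -> np.ndarray:
        """O2 moles summed over liquid and (ideal-gas) headspace."""
        gas = self.xi_o * cfg.pressure_pa * (cfg.v_g_L * 1e-3) / (const.R * cfg.temp_K)
        return self.o_l_mol_per_l * cfg.v_l_L + gas


@dataclass
class SimulationRun:
    live: InstrumentTrace
    dead: InstrumentTrace
    truth: GroundTruth
    config: SimulationConfig
    seed: int


def _specific_rate(cfg: SimulationConfig, p: float, c: float | None) -> float:
    """Specific O2 production (mol g⁻¹ s⁻¹) at incident power p (W)."""
    if p > 0:
        f = p / (cfg.k_m_W + p) if cfg.k_m_W > 0 else 1.0
    else:
        f = 0.0
    lim = c / (cfg.k_c_mol_l + c) if c is not None else 1.0
    return cfg.v_max_mol_g_s * f * lim - cfg.dark_respiration_mol_g_s


def _simulate_truth(cfg: SimulationConfig) -> GroundTruth:
    prog, cal = cfg.program, cfg.calibration
    t = prog.times()
    n = t.size
    dt = prog.sampling_s
    p_full = np.asarray(cal.power_W(prog.current_mA(t), check_range=False), dtype=float)
    p_half = np.asarray(
        cal.power_W(prog.current_mA(t[:-1] + dt / 2.0), check_range=False), dtype=float
    )

    mu_s = cfg.mu_per_h / 3600.0
    o_eq = cfg.k_h * XI_AIR * cfg.pressure_pa
    carbon = cfg.c0_mol_l is not None
    gas_factor = cfg.v_l_L * const.R * cfg.temp_K / (cfg.pressure_pa * cfg.v_g_L * 1e-3)

    X = np.empty(n); C = np.empty(n) if carbon else None
    O = np.empty(n); XI = np.empty(n); CUM = np.empty(n)
    x, c = cfg.x0_g, (cfg.c0_mol_l if carbon else None)
    o, xi, cum = o_eq, XI_AIR, 0.0

    def deriv(state, p):
        x_, c_, o_, xi_ = state
        r_vol = _specific_rate(cfg, p, c_) * x_ / cfg.v_l_L
        exch = cfg.k_v_per_s * (o_ - cfg.k_h * xi_ * cfg.pressure_pa)
        dx = mu_s * x_ if p > 0 else 0.0
        dc = -r_vol if carbon else 0.0
        do = r_vol - exch
        dxi = exch * gas_factor
        dcum = r_vol * cfg.v_l_L
        return dx, dc, do, dxi, dcum

    for i in range(n):
        X[i] = x
        if carbon:
            C[i] = c
        O[i], XI[i], CUM[i] = o, xi, cum
        if i == n - 1:
            break
        p0, pm, p1 = p_full[i], p_half[i], p_full[i + 1]
        s0 = (x, c, o, xi)
        k1 = deriv(s0, p0)
        s1 = (x + dt / 2 * k1[0], (c + dt / 2 * k1[1]) if carbon else None,
              o + dt / 2 * k1[2], xi + dt / 2 * k1[3])
        k2 = deriv(s1, pm)
        s2 = (x + dt / 2 * k2[0], (c + dt / 2 * k2[1]) if carbon else None,
              o + dt / 2 * k2[2], xi + dt / 2 * k2[3])
        k3 = deriv(s2, pm)
        s3 = (x + dt * k3[0], (c + dt * k3[1]) if carbon else None,
              o + dt * k3[2], xi + dt * k3[3])
        k4 = deriv(s3, p1)
        x += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        if carbon:
            c += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            c = max(c, 0.0)
        o += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        xi += dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        cum += dt / 6 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        if not all(np.isfinite(v) for v in (x, o, xi, cum)):
            raise SimulationError(
                f"integrator produced a non-finite state at t={t[i + 1]:g} s",
                state={"x": x, "c": c, "o": o, "xi": xi, "t": float(t[i + 1])},
            )

    r_vol = np.array([
        _specific_rate(cfg, p_full[i], C[i] if carbon else None) * X[i] / cfg.v_l_L
        for i in range(n)
    ])
    p_ps = abs(cfg.oxycal_kj_per_mol) * 1e3 * r_vol * cfg.v_l_L
    pe = np.full(n, np.nan)
    lit = p_full > 1e-12
    pe[lit] = p_ps[lit] / p_full[lit]
    return GroundTruth(
        time_s=t, p_i_W=p_full, p_ps_W=p_ps,
        r_o2_mol_per_l_s=r_vol, R_o2_mol_per_s=r_vol * cfg.v_l_L,
        x_g=X, c_mol_l=C, o_l_mol_per_l=O, xi_o=XI, pe=pe, cum_o2_mol=CUM,
    )


def _base_meta(cfg: SimulationConfig, role: str, seed: int) -> dict:
    meta = {
        "role": role,
        "seed": repr(seed),
        "config_hash": cfg.hash(),
        "sign": "1",
        "k_v_per_s": repr(cfg.k_v_per_s),
        "k_h": repr(cfg.k_h),
        "pressure_pa": repr(cfg.pressure_pa),
        "v_l_L": repr(cfg.v_l_L),
        "v_g_L": repr(cfg.v_g_L),
        "temp_K": repr(cfg.temp_K),
        "x0_g": repr(cfg.x0_g),
        "cn0_per_ml": repr(cfg.cn0_per_ml),
        "o2_gas_units": cfg.o2_gas_units,
    }
    meta.update(cfg.program.to_meta())
    return meta


def _gas_pct(cfg: SimulationConfig, xi: np.ndarray) -> np.ndarray:
    if cfg.o2_gas_units == "percent_volume":
        return xi * 100.0
    return xi / XI_AIR * 100.0


def _make_trace(cfg: SimulationConfig, truth: GroundTruth, rng, role: str, seed: int,
                dead_o_eq: float | None = None) -> InstrumentTrace:
    n = truth.time_s.size
    heat_noise = rng.normal(0.0, cfg.sigma_heat_W, n)
    liq_noise = rng.normal(0.0, cfg.sigma_o2_pct / 100.0, n)
    gas_noise = rng.normal(0.0, cfg.sigma_o2_pct / 100.0, n)
    o_eq = cfg.k_h * XI_AIR * cfg.pressure_pa
    if role == "live":
        dp = cfg.arm_imbalance * truth.p_i_W + truth.p_ps_W + heat_noise
        liq = truth.o_l_mol_per_l / o_eq * 100.0
        gas = _gas_pct(cfg, truth.xi_o)
    else:  # dead suspension stays at air equilibrium
        dp = cfg.arm_imbalance * truth.p_i_W + heat_noise
        liq = np.full(n, 100.0)
        gas = _gas_pct(cfg, np.full(n, XI_AIR))
    return InstrumentTrace(
        time_s=truth.time_s,
        dp_heat_uW=dp * 1e6,
        o2_liquid_pct=liq * (1.0 + liq_noise),
        o2_gas_pct=gas * (1.0 + gas_noise),
        led_current_mA=cfg.program.current_mA(truth.time_s),
        meta=_base_meta(cfg, role, seed),
    )


def simulate_run(cfg: SimulationConfig, seed: int = 0) -> SimulationRun:
    """One paired live/dead run with shared program and ground truth."""
    truth = _simulate_truth(cfg)
    rng = np.random.default_rng(seed)
    live = _make_trace(cfg, truth, rng, "live", seed)
    dead = _make_trace(cfg, truth, rng, "dead", seed)
    return SimulationRun(live=live, dead=dead, truth=truth, config=cfg, seed=seed)


def replicate_batch(
    cfg: SimulationConfig, n: int, seeds=None, base_seed: int = 0
) -> list[SimulationRun]:
    """n runs with independent noise realisations over one ground truth."""
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    if seeds is None:
        seeds = [base_seed + i for i in range(n)]
    seeds = list(seeds)
    if len(seeds) != n:
        raise ValueError("number of seeds must match n")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: replicates will not be independent")
    truth = _simulate_truth(cfg)
    runs = []
    for s in seeds:
        rng = np.random.default_rng(s)
        live = _make_trace(cfg, truth, rng, "live", s)
        dead = _make_trace(cfg, truth, rng, "dead", s)
        runs.append(SimulationRun(live=live, dead=dead, truth=truth, config=cfg, seed=s))
    return runs


def simulate_exchange_only(
    cfg: SimulationConfig,
    duration_s: float = 10800.0,
    o_l0_mol_per_l: float = 0.0,
    seed: int | None = None,
) -> OxygenTrace:
    """Algae-free exchange run for k_V estimation (N2-purged liquid).

    Starts with the configured initial dissolved concentration (default 0,
    i.e. oxygen-free) under an air headspace and integrates the pure
    two-compartment exchange.  With ``seed`` given, multiplicative optode
    noise is applied to both channels.
    """
    dt = cfg.program.sampling_s
    t = np.arange(0.0, duration_s + dt / 2, dt)
    n = t.size
    o_eqf = cfg.k_h * cfg.pressure_pa
    gas_factor = cfg.v_l_L * const.R * cfg.temp_K / (cfg.pressure_pa * cfg.v_g_L * 1e-3)
    O = np.empty(n); XI = np.empty(n)
    o, xi = float(o_l0_mol_per_l), XI_AIR

    def f(o_, xi_):
        exch = cfg.k_v_per_s * (o_ - o_eqf * xi_)
        return -exch, exch * gas_factor

    for i in range(n):
        O[i], XI[i] = o, xi
        if i == n - 1:
            break
        k1 = f(o, xi)
        k2 = f(o + dt / 2 * k1[0], xi + dt / 2 * k1[1])
        k3 = f(o + dt / 2 * k2[0], xi + dt / 2 * k2[1])
        k4 = f(o + dt * k3[0], xi + dt * k3[1])
        o += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        xi += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])

    if seed is not None and cfg.sigma_o2_pct > 0:
        rng = np.random.default_rng(seed)
        O = O * (1.0 + rng.normal(0.0, cfg.sigma_o2_pct / 100.0, n))
        O = np.clip(O, 0.0, None)
        XI = XI * (1.0 + rng.normal(0.0, cfg.sigma_o2_pct / 100.0, n))
    return OxygenTrace(
        time_s=t, o_l_mol_per_l=O, xi_o=XI,
        k_h=cfg.k_h, pressure_pa=cfg.pressure_pa,
        v_l_L=cfg.v_l_L, v_g_L=cfg.v_g_L, temp_K=cfg.temp_K,
    )


def exchange_trace_to_instrument(cfg: SimulationConfig, trace: OxygenTrace) -> InstrumentTrace:
    """Render an exchange-only run in the standard run-CSV channel layout."""
    o_eq = cfg.k_h * XI_AIR * cfg.pressure_pa
    return InstrumentTrace(
        time_s=trace.time_s,
        dp_heat_uW=np.zeros_like(trace.time_s),
        o2_liquid_pct=trace.o_l_mol_per_l / o_eq * 100.0,
        o2_gas_pct=_gas_pct(cfg, trace.xi_o),
        led_current_mA=np.zeros_like(trace.time_s),
        meta=_base_meta(cfg, "exchange", 0),
    )


def carbon_limited_scenario(
    p_max_W: float = 61.1e-3,
    n_ramps: int = 3,
    c0_mol_l: float = 1.5e-3,
    k_c_mol_l: float = 0.5e-3,
    calibration: CalibrationModel | None = None,
) -> SimulationConfig:
    """Study conditions of the dissolved-carbon deficiency experiment.

    A 1.5 mM lumped carbon pool (15% of the usual supplementation) under a
    61.1 mW trapezoidal program.  Growth is disabled: in this forward model
    biomass formation *is* carbon fixation, so a starved pool is
    incompatible with prescribed exponential growth.  The pool throttles the
    O2 rate through ``C/(K_C + C)``, producing a conserved-energy maximum
    before the end of the first plateau and declining ramp maxima
    thereafter.
    """
    cal = calibration or default_calibration()
    program = LightProgram.from_power(p_max_W, cal, n_ramps=n_ramps)
    return SimulationConfig(
        program=program, calibration=cal,
        mu_per_h=0.0, c0_mol_l=c0_mol_l, k_c_mol_l=k_c_mol_l,
    )


def write_truth_json(run: SimulationRun, path) -> None:
    """Sidecar with the full config and ground-truth summaries."""
    truth, cfg = run.truth, run.config
    prog = cfg.program
    plateau_means = []
    for i in range(prog.n_ramps):
        lo, hi = prog.plateau_window(i)
        m = (truth.time_s >= lo) & (truth.time_s < hi)
        plateau_means.append(float(truth.p_ps_W[m].mean()) if m.any() else None)
    payload = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": run.seed,
        "summaries": {
            "p_i_max_W": float(np.max(truth.p_i_W)),
            "p_ps_plateau_mean_W": plateau_means,
            "pe_plateau_mean": [
                float(np.nanmean(truth.pe[(truth.time_s >= lo) & (truth.time_s < hi)]))
                for lo, hi in (prog.plateau_window(i) for i in range(prog.n_ramps))
            ],
            "x_final_g": float(truth.x_g[-1]),
            "cum_o2_mol": float(truth.cum_o2_mol[-1]),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (CalibrationModel,)):
        return obj.to_dict()
    return str(obj)
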