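"""Derived photosynthetic parameters.

Everything downstream of the reduced series lives here: the
calorespirometric (oxycaloric) ratio, saturation (Michaelis–Menten-like)
fits of the light response, the specific growth rate from repeated ramp
maxima, biomass conversions (optical density -> dry weight / cell number,
elemental-formula molar mass), the photon budget of CO2 fixation, and the
Hess-law bookkeeping of side reactions such as the Mehler (water–water)
cycle.

Conventions
-----------
* Regressions are ordinary least squares with intercept; no
  errors-in-variables correction (documented limitation).
* Ratios of conserved energy to O2 are reported negative (enthalpy
  convention: energy-conserving photosynthesis has a negative ratio in
  kJ per mol O2), while internal slopes are positive W per (mol s⁻¹).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .optics import FitConvergenceError, LightProgram

#: Mean oxycaloric equivalent of carbohydrate metabolism (kJ per mol O2);
#: literature span roughly −430 to −480.
OXYCALORIC_DEFAULT_KJ_PER_MOL = -455.0

ATOMIC_MASSES = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "P": 30.974, "S": 32.06,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)([0-9]*\.?[0-9]*)")


# ---------------------------------------------------------------------------
# calorespirometric ratio
# ---------------------------------------------------------------------------

@dataclass
class CalorespROutput:
    """OLS relation between conserved energy flow and O2 production rate."""

    ratio_kj_per_mol: float      # −slope, enthalpy convention
    se_kj_per_mol: float
    intercept_W: float
    pearson_r: float
    p_slope: float
    n: int


def calorespirometric_ratio(p_ps_W, R_o2_mol_per_s) -> CalorespROutput:
    """Fit ``P_PS = slope·R_O2 + b`` and report ``−slope`` in kJ mol⁻¹.

    Requires at least 10 paired points spanning a range of rates.
    """
    y = np.asarray(p_ps_W, dtype=float)
    x = np.asarray(R_o2_mol_per_s, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need at least 10 paired points")
    if np.ptp(x) <= 0 or float(np.std(x)) == 0.0:
        raise ValueError("oxygen rates show no spread; slope is undefined")
    res = stats.linregress(x, y)
    return CalorespROutput(
        ratio_kj_per_mol=-float(res.slope) / 1e3,
        se_kj_per_mol=float(res.stderr) / 1e3,
        intercept_W=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_slope=float(res.pvalue),
        n=int(x.size),
    )


def scale_oxygen_to_power(R_o2_mol_per_s, oxycal_kj_per_mol: float = OXYCALORIC_DEFAULT_KJ_PER_MOL):
    """Scale an O2 rate to an energy flow with an oxycaloric equivalent (W)."""
    r = np.asarray(R_o2_mol_per_s, dtype=float)
    out = abs(oxycal_kj_per_mol) * 1e3 * r
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# light-response saturation
# ---------------------------------------------------------------------------

@dataclass
class SaturationFit:
    """``v = v_max·P_I/(k_m + P_I)`` — saturation of the light response."""

    v_max: float
    k_m_W: float
    v_max_se: float
    k_m_se: float
    n: int

    def predict(self, p_i_W):
        p = np.asarray(p_i_W, dtype=float)
        out = self.v_max * p / (self.k_m_W + p)
        return float(out) if out.ndim == 0 else out


def fit_saturation(p_i_W, v) -> SaturationFit:
    """Nonlinear least squares of the Michaelis–Menten-like light response.

    Initialised with ``v_max = max(v)`` and ``k_m`` at the half-maximum
    abscissa.  Requires at least 5 points whose P_I range brackets k_m for a
    well-conditioned fit.
    """
    p = np.asarray(p_i_W, dtype=float)
    y = np.asarray(v, dtype=float)
    ok = np.isfinite(p) & np.isfinite(y)
    p, y = p[ok], y[ok]
    if p.size < 5:
        raise ValueError("need at least 5 points")
    vmax0 = float(y.max())
    half = vmax0 / 2.0
    km0 = float(np.interp(half, np.sort(y), p[np.argsort(y)]))
    km0 = max(km0, 1e-6 * float(p.max()) or 1e-9)

    def model(pp, vm, km):
        return vm * pp / (km + pp)

    try:
        popt, pcov = curve_fit(
            model, p, y, p0=[vmax0, km0], bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise FitConvergenceError(f"saturation fit did not converge: {err}") from err
    se = np.sqrt(np.diag(pcov))
    return SaturationFit(
        v_max=float(popt[0]), k_m_W=float(popt[1]),
        v_max_se=float(se[0]), k_m_se=float(se[1]), n=int(p.size),
    )


def ratio_of_vmax(fit_energy: SaturationFit, fit_oxygen: SaturationFit) -> tuple[float, float]:
    """Oxycaloric equivalent from the two saturation amplitudes (kJ mol⁻¹).

    ``−(v_max,energy / v_max,O2)/1e3`` with the standard error by
    first-order propagation.  Returns ``(value, se)``.
    """
    if fit_oxygen.v_max == 0:
        raise ValueError("oxygen v_max is zero")
    ratio = -(fit_energy.v_max / fit_oxygen.v_max) / 1e3
    rel = np.sqrt(
        (fit_energy.v_max_se / fit_energy.v_max) ** 2
        + (fit_oxygen.v_max_se / fit_oxygen.v_max) ** 2
    )
    return float(ratio), float(abs(ratio) * rel)


# ---------------------------------------------------------------------------
# growth from repeated ramps
# ---------------------------------------------------------------------------

@dataclass
class GrowthEstimate:
    mu_per_h: float
    source: str
    ramp_maxima: np.ndarray | None = None
    delta_t_h: float | None = None


def growth_rate(x_first_max: float, x_last_max: float, delta_t_h: float,
                source: str = "heat") -> GrowthEstimate:
    """Specific growth rate from the exponential growth of ramp maxima.

    ``µ = ln(X_last/X_first)/Δt`` — translation-invariant in time and
    scale-invariant in X.
    """
    if x_first_max <= 0 or x_last_max <= 0:
        raise ValueError("ramp maxima must be positive")
    if delta_t_h <= 0:
        raise ValueError("elapsed time must be positive")
    return GrowthEstimate(
        mu_per_h=float(np.log(x_last_max / x_first_max) / delta_t_h), source=source
    )


def ramp_maxima(time_s, series, program: LightProgram, smooth_s: float = 300.0) -> np.ndarray:
    """Maximum of a moving mean over each ramp window.

    Raw maxima are noise-dominated (heat noise ~25 µW), so each ramp's
    maximum is taken from a ``smooth_s`` moving average.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(series, dtype=float)
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_s / dt)))
    sm = np.convolve(y, np.ones(w) / w, mode="same")
    out = []
    for i in range(program.n_ramps):
        lo, hi = program.ramp_window(i)
        m = (t >= lo) & (t < hi)
        if not m.any():
            raise ValueError(f"series does not cover ramp {i}")
        out.append(float(np.nanmax(sm[m])))
    return np.asarray(out)


def growth_rate_from_ramps(
    time_s, series, program: LightProgram, smooth_s: float = 300.0, source: str = "heat"
) -> GrowthEstimate:
    """µ from the first and last ramp maxima of a repeated-ramp run.

    Ramp maxima of a growing culture recur at the same program phase, so the
    elapsed time is ``(n_ramps − 1)`` ramp periods.
    """
    if program.n_ramps < 2:
        raise ValueError("need at least two ramps to estimate growth")
    maxima = ramp_maxima(time_s, series, program, smooth_s)
    dt_h = (program.n_ramps - 1) * program.ramp_duration_s / 3600.0
    est = growth_rate(maxima[0], maxima[-1], dt_h, source=source)
    est.ramp_maxima = maxima
    est.delta_t_h = dt_h
    return est


# ---------------------------------------------------------------------------
# biomass scaling relations
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    pearson_r: float
    p_slope: float
    p_intercept: float
    n: int


def pps_vs_cells(cell_number_per_ml, delta_p) -> LinearFit:
    """OLS of the differential heat signal against cell number.

    Units follow the inputs (e.g. µW against cells mL⁻¹ gives a slope in
    µW·mL).  Reports Pearson r and two-sided t-test p-values for slope and
    intercept.
    """
    x = np.asarray(cell_number_per_ml, dtype=float)
    y = np.asarray(delta_p, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct cell numbers")
    res = stats.linregress(x, y)
    dof = x.size - 2
    if res.intercept_stderr > 0:
        t_int = res.intercept / res.intercept_stderr
        p_int = 2.0 * stats.t.sf(abs(t_int), dof)
    else:
        p_int = 0.0 if res.intercept != 0 else 1.0
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_se=float(res.stderr), intercept_se=float(res.intercept_stderr),
        pearson_r=float(res.rvalue), p_slope=float(res.pvalue),
        p_intercept=float(p_int), n=int(x.size),
    )


def cell_specific_power(
    slope_uW_ml_per_cell: float, v_l_mL: float = 10.0, slope_se: float | None = None
) -> tuple[float, float | None]:
    """Cell-specific conserved power (pW cell⁻¹) from the heat-vs-CN slope.

    The regression slope has units µW·mL per cell for a suspension of volume
    ``v_l_mL``; dividing by the volume and converting µW -> pW gives the
    per-cell power.  Returns ``(value, se)``.
    """
    if v_l_mL <= 0:
        raise ValueError("suspension volume must be positive")
    factor = 1e6 / v_l_mL  # µW·mL/cell -> pW/cell
    se = slope_se * factor if slope_se is not None else None
    return slope_uW_ml_per_cell * factor, se


@dataclass
class BiomassModel:
    """Optical-density conversions and mean elemental composition."""

    cdw_per_od_g_per_l: float = 0.353
    cdw_per_od_se: float = 0.013
    cells_per_od_per_ml: float = 6.72e6
    cells_per_od_se: float = 0.20e6
    formula: str = "CH1.821O0.605N0.103"

    def molar_mass(self) -> float:
        return biomass_molar_mass(self.formula)


def cell_dry_mass(bm: BiomassModel) -> tuple[float, float]:
    """Mean cell dry mass (pg cell⁻¹) from the two OD conversion slopes.

    ``CDW/OD [g L⁻¹] / (CN/OD [mL⁻¹] · 1000)`` in pg; SE by first-order
    propagation of the two slope uncertainties.
    """
    if bm.cdw_per_od_g_per_l <= 0 or bm.cells_per_od_per_ml <= 0:
        raise ValueError("conversion slopes must be positive")
    mass_g = bm.cdw_per_od_g_per_l / 1e3 / bm.cells_per_od_per_ml
    pg = mass_g * 1e12
    rel = np.sqrt(
        (bm.cdw_per_od_se / bm.cdw_per_od_g_per_l) ** 2
        + (bm.cells_per_od_se / bm.cells_per_od_per_ml) ** 2
    )
    return float(pg), float(pg * rel)


def biomass_molar_mass(formula: str | dict) -> float:
    """Molar mass (g mol⁻¹) of an elemental composition like CH1.821O0.605N0.103.

    Accepts a formula string with fractional stoichiometric indices or a
    ``{element: index}`` mapping; unknown element symbols raise.
    """
    if isinstance(formula, str):
        comp: dict[str, float] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            comp[m.group(1)] = comp.get(m.group(1), 0.0) + float(m.group(2) or 1.0)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    else:
        comp = dict(formula)
    mass = 0.0
    for el, idx in comp.items():
        if el not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {el!r}")
        if idx < 0:
            raise ValueError("stoichiometric indices must be non-negative")
        mass += ATOMIC_MASSES[el] * idx
    return mass


# ---------------------------------------------------------------------------
# photon budget and Hess-law bookkeeping
# ---------------------------------------------------------------------------

#: Theoretical minimum number of photons per CO2 fixed.
QUANTUM_REQUIREMENT_FLOOR = 8.0


@dataclass
class PhotonBudget:
    photons_per_co2: float
    g_per_einstein: float
    absorbed_e_per_s: float
    below_theoretical_floor: bool


def photon_budget(
    flow_uE_per_s: float,
    absorbed_fraction: float,
    mu_per_h: float,
    x0_g: float,
    molar_mass_g_per_mol: float,
) -> PhotonBudget:
    """Photon requirement of CO2 fixation and biomass yield on light.

    absorbed flux   = absorbed_fraction · Φ            (E s⁻¹)
    biomass rate    = µ·X0                             (g s⁻¹)
    C-fixation rate = biomass rate / molar mass        (mol C s⁻¹)

    Returns photons per CO2 fixed and g biomass per einstein absorbed; their
    product equals the molar mass exactly (algebraic identity).  A result
    below the theoretical floor of 8 photons per CO2 is physically
    impossible and triggers a warning.
    """
    if flow_uE_per_s <= 0 or mu_per_h <= 0 or x0_g <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("all photon-budget inputs must be positive")
    if not 0 < absorbed_fraction <= 1:
        raise ValueError("absorbed fraction must lie in (0, 1]")
    absorbed = absorbed_fraction * flow_uE_per_s * 1e-6  # E/s
    biomass_rate = mu_per_h / 3600.0 * x0_g              # g/s
    cfix = biomass_rate / molar_mass_g_per_mol           # mol C/s
    photons = absorbed / cfix
    below = photons < QUANTUM_REQUIREMENT_FLOOR
    if below:
        warnings.warn(
            f"photon requirement {photons:.2f} is below the theoretical "
            f"minimum of {QUANTUM_REQUIREMENT_FLOOR:g} photons per CO2",
            stacklevel=2,
        )
    return PhotonBudget(
        photons_per_co2=float(photons),
        g_per_einstein=float(biomass_rate / absorbed),
        absorbed_e_per_s=float(absorbed),
        below_theoretical_floor=bool(below),
    )


def reaction_ratio(
    delta_h_photo_kj_per_mol: float,
    n_o2_photo: float,
    delta_h_side_kj_per_mol: float = 0.0,
    n_o2_side: float = 0.0,
    side_per_photo: float = 0.0,
) -> float:
    """Hess-law calorespirometric ratio of photosynthesis plus a side reaction.

    For glucose photosynthesis (ΔH = +2813.6 kJ, 6 O2 formed) alone the
    ratio is −2813.6/6 = −469 kJ per mol O2.  A side reaction consuming
    ``n_o2_side`` O2 with enthalpy ``delta_h_side`` running
    ``side_per_photo`` times per photosynthesis event shifts it to
    ``−(ΔH_photo + mix·ΔH_side)/(n_O2_photo − mix·n_O2_side)``.
    """
    net_o2 = n_o2_photo - side_per_photo * n_o2_side
    if net_o2 == 0:
        raise ValueError("net O2 turnover is zero; the ratio is undefined")
    return -(delta_h_photo_kj_per_mol + side_per_photo * delta_h_side_kj_per_mol) / net_o2
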