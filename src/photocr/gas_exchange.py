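"""Oxygen optode reduction: Henry-law conversion, k_V estimation and r_O2.

The ampoule is closed, so dissolved O2 exchanges with the headspace at a
first-order rate k_V (s⁻¹).  The biological production rate is recovered
from the liquid and headspace optode channels by correcting the liquid
accumulation for that exchange:

    r_O2 = dO_L/dt + k_V · (O_L − k_H·ξ_O·π)

with O_L the dissolved concentration (mol L⁻¹), ξ_O the headspace O2 volume
fraction, k_H the Henry coefficient (mol L⁻¹ Pa⁻¹) and π the total pressure
(Pa).  k_V is estimated from an algae-free run started far from equilibrium
(N2-purged liquid) by regressing dO_L/dt on the driving force, whose slope
is −k_V.  Derivatives are taken with a Savitzky–Golay local-polynomial
filter because the raw optode signal is noisy relative to the hour-scale
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

#: O2 volume fraction of air, used for % air-saturation conversions.
XI_AIR = 0.2095
#: Default Henry coefficient under measurement conditions (mol L⁻¹ Pa⁻¹).
#: An alternative tabulated value of 1.25e-8 can be passed explicitly.
HENRY_DEFAULT = 1.3e-8
PRESSURE_DEFAULT = 101325.0


def percent_to_concentration(
    reading_pct,
    k_h: float = HENRY_DEFAULT,
    pressure_pa: float = PRESSURE_DEFAULT,
    xi_air: float = XI_AIR,
):
    """Dissolved O2 (mol L⁻¹) from a % air-saturation optode reading.

    100% air saturation corresponds to equilibrium with air:
    ``O_L = k_H·ξ_air·π`` (2.76e-4 mol L⁻¹ at the defaults).
    """
    reading = np.asarray(reading_pct, dtype=float)
    if np.any(reading < 0):
        raise ValueError("optode reading must be non-negative")
    out = reading / 100.0 * k_h * xi_air * pressure_pa
    return float(out) if out.ndim == 0 else out


@dataclass
class OxygenTrace:
    """Synchronized dissolved/headspace O2 series with vessel constants."""

    time_s: np.ndarray
    o_l_mol_per_l: np.ndarray
    xi_o: np.ndarray | None  # headspace O2 volume fraction
    k_h: float = HENRY_DEFAULT
    pressure_pa: float = PRESSURE_DEFAULT
    v_l_L: float = 0.010
    v_g_L: float = 0.010
    temp_K: float = 293.15

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o_l_mol_per_l = np.asarray(self.o_l_mol_per_l, dtype=float)
        if self.xi_o is not None:
            self.xi_o = np.asarray(self.xi_o, dtype=float)
            if np.any((self.xi_o < 0) | (self.xi_o > 1)):
                raise ValueError("headspace O2 volume fraction must lie in [0, 1]")
        if np.any(self.o_l_mol_per_l < -1e-12):
            raise ValueError("dissolved O2 must be non-negative")
        if self.v_l_L <= 0 or self.v_g_L <= 0:
            raise ValueError("volumes must be positive")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def equilibrium_o_l(self) -> np.ndarray:
        """Liquid concentration in equilibrium with the current headspace."""
        if self.xi_o is None:
            raise ValueError("headspace channel missing; gas-exchange correction impossible")
        return self.k_h * self.xi_o * self.pressure_pa

    def driving_force(self) -> np.ndarray:
        return self.o_l_mol_per_l - self.equilibrium_o_l()

    @classmethod
    def from_instrument(
        cls,
        trace,
        k_h: float = HENRY_DEFAULT,
        pressure_pa: float = PRESSURE_DEFAULT,
        v_l_L: float = 0.010,
        v_g_L: float = 0.010,
        temp_K: float = 293.15,
        gas_units: str = "percent_volume",
        xi_air: float = XI_AIR,
    ) -> "OxygenTrace":
        """Build from a raw run (``o2_liquid_pct`` is % air saturation;
        ``o2_gas_pct`` dialect selected by ``gas_units``)."""
        o_l = percent_to_concentration(trace.o2_liquid_pct, k_h, pressure_pa, xi_air)
        gas = np.asarray(trace.o2_gas_pct, dtype=float)
        if gas_units == "percent_volume":
            xi = gas / 100.0
        elif gas_units == "percent_air_saturation":
            xi = gas / 100.0 * xi_air
        else:
            raise ValueError(f"unknown headspace dialect {gas_units!r}")
        return cls(
            time_s=trace.time_s, o_l_mol_per_l=o_l, xi_o=xi,
            k_h=k_h, pressure_pa=pressure_pa, v_l_L=v_l_L, v_g_L=v_g_L, temp_K=temp_K,
        )


def _window_samples(window_s: float, dt_s: float, n: int) -> int:
    w = int(round(window_s / dt_s))
    w = max(w, 3)
    if w % 2 == 0:
        w += 1
    if w > n:
        raise ValueError(f"smoothing window ({window_s:g} s) longer than the trace")
    return w


def smooth_derivative(y, dt_s: float, window_s: float = 301.0, polyorder: int = 2):
    """Savitzky–Golay first derivative of a uniformly sampled series."""
    y = np.asarray(y, dtype=float)
    w = _window_samples(window_s, dt_s, y.size)
    return savgol_filter(y, w, polyorder, deriv=1, delta=dt_s, mode="interp")


def smooth(y, dt_s: float, window_s: float = 301.0, polyorder: int = 2):
    """Savitzky–Golay smoothed copy of a uniformly sampled series."""
    y = np.asarray(y, dtype=float)
    w = _window_samples(window_s, dt_s, y.size)
    return savgol_filter(y, w, polyorder, mode="interp")


@dataclass
class ExchangeFit:
    k_v_per_s: float
    stderr_per_s: float
    intercept: float
    intercept_stderr: float
    r_value: float
    n: int


def fit_kv(
    trace: OxygenTrace,
    window_s: float = 301.0,
    polyorder: int = 2,
) -> ExchangeFit:
    """Estimate the gas-exchange coefficient from an algae-free run.

    Regresses the smoothed dO_L/dt on the (smoothed) driving force
    ``O_L − k_H·ξ_O·π``; ``k_V = −slope``.  The intercept is reported as a
    diagnostic (it should be ≈ 0 for a purely physical exchange).  Half a
    smoothing window is trimmed at each end to avoid boundary artefacts.

    The run must start far from equilibrium; a trace whose driving force
    never rises above the optode noise is unidentifiable and raises.
    """
    dt = trace.dt_s
    deriv = smooth_derivative(trace.o_l_mol_per_l, dt, window_s, polyorder)
    drive = smooth(trace.driving_force(), dt, window_s, polyorder)

    w = _window_samples(window_s, dt, trace.o_l_mol_per_l.size)
    sl = slice(w // 2, trace.o_l_mol_per_l.size - w // 2)
    deriv, drive = deriv[sl], drive[sl]
    if deriv.size < 10:
        raise ValueError("trace too short to estimate k_V")

    noise = float(np.std(np.diff(trace.o_l_mol_per_l))) / np.sqrt(2.0)
    span = float(np.ptp(drive))
    if span <= max(10.0 * noise, 0.02 * trace.k_h * XI_AIR * trace.pressure_pa):
        raise ValueError(
            "driving force never exceeds the noise level: k_V is unidentifiable "
            "(the run must start far from gas/liquid equilibrium)"
        )
    res = stats.linregress(drive, deriv)
    return ExchangeFit(
        k_v_per_s=-float(res.slope),
        stderr_per_s=float(res.stderr),
        intercept=float(res.intercept),
        intercept_stderr=float(res.intercept_stderr),
        r_value=float(res.rvalue),
        n=int(deriv.size),
    )


@dataclass
class RateSeries:
    time_s: np.ndarray
    r_o2_mol_per_l_s: np.ndarray  # volumetric production rate
    R_o2_mol_per_s: np.ndarray    # volume-integrated rate, r·V_L


def production_rate(
    trace: OxygenTrace,
    k_v_per_s: float,
    window_s: float = 301.0,
    polyorder: int = 2,
) -> RateSeries:
    """Gas-exchange-corrected O2 production rate (production positive).

    ``r_O2 = dO_L/dt + k_V·(O_L − k_H·ξ_O·π)`` pointwise; with ``k_V = 0``
    this degenerates to the raw smoothed derivative.
    """
    if k_v_per_s < 0:
        raise ValueError("k_V must be non-negative")
    if trace.xi_o is None:
        raise ValueError("headspace channel missing; gas-exchange correction impossible")
    dt = trace.dt_s
    deriv = smooth_derivative(trace.o_l_mol_per_l, dt, window_s, polyorder)
    drive = smooth(trace.driving_force(), dt, window_s, polyorder)
    r = deriv + k_v_per_s * drive
    return RateSeries(
        time_s=trace.time_s, r_o2_mol_per_l_s=r, R_o2_mol_per_s=r * trace.v_l_L
    )


M_O2_G_PER_MOL = 32.0


@dataclass
class SpecificRates:
    per_gram_mol_g_s: float
    per_cell_fmol_h: float | None
    mg_o2_per_g_h: float


def specific_rates(
    R_o2_mol_per_s: float, biomass_g: float, cells: float | None = None
) -> SpecificRates:
    """Biomass- and cell-specific O2 rates with standard unit conversions.

    Returns the dry-mass-specific rate (mol g⁻¹ s⁻¹), the per-cell rate in
    fmol cell⁻¹ h⁻¹ (1 fmol = 1e-15 mol) and the mass rate in
    mg O2 g⁻¹ h⁻¹ (M_O2 = 32 g mol⁻¹).
    """
    if biomass_g <= 0:
        raise ValueError("biomass must be positive")
    per_gram = R_o2_mol_per_s / biomass_g
    per_cell = None
    if cells is not None:
        if cells <= 0:
            raise ValueError("cell count must be positive")
        per_cell = R_o2_mol_per_s / cells * 3600.0 / 1e-15
    return SpecificRates(
        per_gram_mol_g_s=per_gram,
        per_cell_fmol_h=per_cell,
        mg_o2_per_g_h=per_gram * M_O2_G_PER_MOL * 3600.0 * 1e3,
    )
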