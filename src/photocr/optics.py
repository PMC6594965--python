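"""LED optics: photon energetics, drive-current calibration and light programs.

The instrument illuminates a closed calorimetric vessel through a two-arm
light guide driven by a high-power blue LED (treated as monochromatic,
default 455 nm).  This module converts between the optical quantities the
reduction needs:

* drive current ``I_LED`` (mA) -> radiation flow ``Phi`` (µE s⁻¹, where
  1 einstein E = 1 mol photons), via a degree-3 calibration polynomial
  constrained through the origin (no current, no light);
* radiation flow -> incident radiant power ``P_I`` (W), via the photon
  energy ``E_P = h·c/λ``;
* distance from the light-guide output -> irradiance, via a two-parameter
  exponential decay ``IR(δ) = IR₀ + A·(exp(B·δ) − 1)`` with ``B < 0``;
* surface irradiance ``IR₀`` -> radiation flow, by multiplying with the
  emitting area ``(π/4)·d²`` of the guide output.

It also defines :class:`LightProgram`, the trapezoidal irradiation schedule
(linear rise, plateau, linear fall, repeated ``n_ramps`` times) shared by
the simulator and the reduction pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import constants as const
from scipy.optimize import brentq, least_squares


class FitConvergenceError(RuntimeError):
    """Raised when a nonlinear fit fails; carries the last iterate."""

    def __init__(self, message: str, last_params=None, residual_norm=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual_norm = residual_norm


def photon_energy(wavelength_m: float) -> float:
    """Energy of one photon, ``E_P = h·c/λ`` in J.

    ``wavelength_m`` must be positive (455 nm -> 4.366e-19 J).
    """
    if wavelength_m <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_m}")
    return const.h * const.c / wavelength_m


def einstein_energy(wavelength_m: float) -> float:
    """Energy of one mole of photons, ``N_A·E_P`` in J per einstein."""
    return const.N_A * photon_energy(wavelength_m)


def radiant_power(flow_e_per_s, wavelength_m: float):
    """Incident radiant power ``P_I = Φ·N_A·E_P`` in W.

    Parameters
    ----------
    flow_e_per_s : float or ndarray
        Radiation flow Φ in einstein (mol photons) per second; must be
        non-negative.
    wavelength_m : float
        Wavelength in m.
    """
    flow = np.asarray(flow_e_per_s, dtype=float)
    if np.any(flow < 0):
        raise ValueError("radiation flow must be non-negative")
    out = flow * einstein_energy(wavelength_m)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationModel:
    """Current -> radiation-flow calibration plus irradiance decay with distance.

    Attributes
    ----------
    current_poly : tuple of 3 floats
        ``(c1, c2, c3)`` of ``Φ(I) = c1·I + c2·I² + c3·I³`` with I in mA and
        Φ in µE s⁻¹.  The polynomial has no constant term: zero current gives
        zero light.
    wavelength_nm : float
        Emission wavelength used for the photon energy (monochromatic
        treatment).
    current_range_mA : (lo, hi)
        Calibrated current range; evaluation outside it emits a warning
        (ramps are extrapolated continuously, so this is not an error).
    ir0_uE_m2_s, decay_A_uE_m2_s, decay_B_per_mm : float or None
        Parameters of the irradiance-vs-distance model
        ``IR(δ) = IR₀ + A·(exp(B·δ) − 1)``; optional.
    diameter_mm : float
        Effective diameter of the optical output of the light guide.
    """

    current_poly: tuple[float, float, float]
    wavelength_nm: float = 455.0
    current_range_mA: tuple[float, float] = (0.0, 500.0)
    ir0_uE_m2_s: float | None = None
    decay_A_uE_m2_s: float | None = None
    decay_B_per_mm: float | None = None
    diameter_mm: float = 26.0

    def __post_init__(self):
        if len(self.current_poly) != 3:
            raise ValueError("current_poly must have exactly 3 coefficients")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.diameter_mm <= 0:
            raise ValueError("output diameter must be positive")
        lo, hi = self.current_range_mA
        grid = np.linspace(lo, hi, 201)
        if np.any(np.diff(self._eval(grid)) < -1e-12):
            warnings.warn(
                "current->flow polynomial is not monotone non-decreasing over "
                f"the calibrated range {self.current_range_mA} mA",
                stacklevel=2,
            )

    # ---- current -> light ------------------------------------------------
    def _eval(self, i_mA):
        c1, c2, c3 = self.current_poly
        i = np.asarray(i_mA, dtype=float)
        return i * (c1 + i * (c2 + i * c3))

    def flow_uE_per_s(self, i_mA, check_range: bool = True):
        """Radiation flow Φ in µE s⁻¹ for a drive current in mA."""
        i = np.asarray(i_mA, dtype=float)
        lo, hi = self.current_range_mA
        if check_range and (np.any(i < lo - 1e-9) or np.any(i > hi + 1e-9)):
            warnings.warn(
                f"current outside the calibrated range {self.current_range_mA} mA; "
                "extrapolating the calibration polynomial",
                stacklevel=2,
            )
        out = self._eval(i)
        return float(out) if out.ndim == 0 else out

    def flow_e_per_s(self, i_mA, **kw):
        """Radiation flow Φ in E s⁻¹ (SI-style mol photons per second)."""
        return self.flow_uE_per_s(i_mA, **kw) * 1e-6

    def power_W(self, i_mA, **kw):
        """Incident radiant power P_I in W for a drive current in mA."""
        return radiant_power(self.flow_e_per_s(i_mA, **kw), self.wavelength_nm * 1e-9)

    # ---- distance decay --------------------------------------------------
    def irradiance_at(self, delta_mm):
        """Irradiance (µE m⁻² s⁻¹) at distance δ (mm) from the guide output."""
        if None in (self.ir0_uE_m2_s, self.decay_A_uE_m2_s, self.decay_B_per_mm):
            raise ValueError("distance-decay parameters are not set")
        d = np.asarray(delta_mm, dtype=float)
        out = self.ir0_uE_m2_s + self.decay_A_uE_m2_s * (
            np.exp(self.decay_B_per_mm * d) - 1.0
        )
        return float(out) if out.ndim == 0 else out

    # ---- construction / persistence -------------------------------------
    @classmethod
    def fit_current_to_flow(cls, current_mA, flow_uE_per_s, **kwargs) -> "CalibrationModel":
        """Fit the degree-3 through-origin polynomial to (current, flow) pairs.

        With exactly three calibration points the polynomial is exactly
        determined; with more it is a least-squares fit.
        """
        i = np.asarray(current_mA, dtype=float)
        phi = np.asarray(flow_uE_per_s, dtype=float)
        if i.size < 3:
            raise ValueError("need at least 3 calibration points")
        design = np.column_stack([i, i**2, i**3])
        coeffs, *_ = np.linalg.lstsq(design, phi, rcond=None)
        kwargs.setdefault("current_range_mA", (0.0, float(i.max())))
        return cls(current_poly=tuple(float(c) for c in coeffs), **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        # external key names of the calibration-file contract
        return {
            "wavelength_nm": d["wavelength_nm"],
            "current_flow_poly": list(d["current_poly"]),
            "current_range_mA": list(d["current_range_mA"]),
            "ir0": d["ir0_uE_m2_s"],
            "A": d["decay_A_uE_m2_s"],
            "B": d["decay_B_per_mm"],
            "diameter_mm": d["diameter_mm"],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            current_poly=tuple(float(c) for c in d["current_flow_poly"]),
            wavelength_nm=float(d.get("wavelength_nm", 455.0)),
            current_range_mA=tuple(d.get("current_range_mA", (0.0, 500.0))),
            ir0_uE_m2_s=d.get("ir0"),
            decay_A_uE_m2_s=d.get("A"),
            decay_B_per_mm=d.get("B"),
            diameter_mm=float(d.get("diameter_mm", 26.0)),
        )

    def save_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Factory calibration of the reference instrument: the three printed
#: calibration triples (100 mA -> 0.074, 300 mA -> 0.232, 500 mA -> 0.402 µE/s)
#: exactly determine the through-origin cubic.
def default_calibration() -> CalibrationModel:
    return CalibrationModel.fit_current_to_flow(
        [100.0, 300.0, 500.0], [0.074, 0.232, 0.402]
    )


def current_to_flow(cal: CalibrationModel, i_mA, check_range: bool = True):
    """Module-level wrapper of :meth:`CalibrationModel.flow_uE_per_s`."""
    return cal.flow_uE_per_s(i_mA, check_range=check_range)


@dataclass
class DistanceDecayFit:
    ir0_uE_m2_s: float
    A_uE_m2_s: float
    B_per_mm: float
    stderr: tuple[float, float, float]
    residual_norm: float
    n: int

    def predict(self, delta_mm):
        d = np.asarray(delta_mm, dtype=float)
        out = self.ir0_uE_m2_s + self.A_uE_m2_s * (np.exp(self.B_per_mm * d) - 1.0)
        return float(out) if out.ndim == 0 else out


def fit_distance_decay(delta_mm, ir_uE_m2_s) -> DistanceDecayFit:
    """Nonlinear least squares of ``IR = IR₀ + A·(exp(B·δ) − 1)``, B < 0.

    Initialisation: IR₀ from the smallest distance, A from the observed drop,
    B from the span of distances.  At least 4 distinct distances are required.
    """
    d = np.asarray(delta_mm, dtype=float)
    ir = np.asarray(ir_uE_m2_s, dtype=float)
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct distances")
    order = np.argsort(d)
    d, ir = d[order], ir[order]

    ir0_0 = float(ir[0])
    drop = ir0_0 - ir
    a0 = max(float(drop.max()), 1e-6 * max(abs(ir0_0), 1.0))
    span = float(d.max() - d.min()) or 1.0
    b0 = -3.0 / span

    def resid(p):
        ir0, a, b = p
        return ir0 + a * (np.exp(b * d) - 1.0) - ir

    res = least_squares(
        resid,
        x0=[ir0_0, a0, b0],
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, 0.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise FitConvergenceError(
            f"distance-decay fit did not converge: {res.message}",
            last_params=tuple(res.x),
            residual_norm=float(np.linalg.norm(res.fun)),
        )
    # parameter covariance from the Jacobian at the solution
    m = d.size - 3
    rss = float(res.fun @ res.fun)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * (rss / m if m > 0 else np.nan)
        se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    except np.linalg.LinAlgError:
        se = (np.nan, np.nan, np.nan)
    return DistanceDecayFit(
        ir0_uE_m2_s=float(res.x[0]),
        A_uE_m2_s=float(res.x[1]),
        B_per_mm=float(res.x[2]),
        stderr=se,
        residual_norm=float(np.linalg.norm(res.fun)),
        n=int(d.size),
    )


def flow_from_surface_irradiance(ir0_uE_m2_s: float, diameter_m: float) -> float:
    """Radiation flow Φ (E s⁻¹) from the guide-output irradiance IR₀.

    Φ = IR₀ · (π/4)·d² · 1e-6 — irradiance times the emitting area, with the
    µE -> E conversion.
    """
    if diameter_m <= 0:
        raise ValueError("output diameter must be positive")
    if ir0_uE_m2_s < 0:
        raise ValueError("irradiance must be non-negative")
    area = np.pi / 4.0 * diameter_m**2
    return ir0_uE_m2_s * area * 1e-6


@dataclass(frozen=True)
class LightProgram:
    """Trapezoidal irradiation schedule in the drive-current domain.

    Each ramp is a linear current rise over ``rise_s``, a plateau of
    ``plateau_s`` at ``i_max_mA`` and a linear fall over ``fall_s``; ramps
    repeat back to back ``n_ramps`` times after a dark ``lead_in_s`` used for
    baseline estimation.  Times are seconds since run start.
    """

    rise_s: float = 3600.0
    plateau_s: float = 1800.0
    fall_s: float = 3600.0
    n_ramps: int = 1
    lead_in_s: float = 600.0
    tail_s: float = 0.0
    i_max_mA: float = 100.0
    sampling_s: float = 1.0

    def __post_init__(self):
        if min(self.rise_s, self.fall_s) <= 0 or self.plateau_s < 0:
            raise ValueError("ramp segments must have positive rise/fall and non-negative plateau")
        if self.n_ramps < 1:
            raise ValueError("need at least one ramp")
        if self.i_max_mA < 0 or self.sampling_s <= 0 or self.lead_in_s < 0:
            raise ValueError("invalid program parameters")

    @property
    def ramp_duration_s(self) -> float:
        return self.rise_s + self.plateau_s + self.fall_s

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + self.n_ramps * self.ramp_duration_s + self.tail_s

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + self.sampling_s / 2, self.sampling_s)

    def phase(self, t):
        """Dimensionless trapezoid profile u(t) in [0, 1]."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        s = t - self.lead_in_s
        k = np.floor(s / self.ramp_duration_s)
        r = s - k * self.ramp_duration_s
        u = np.zeros_like(t)
        active = (s >= 0) & (k < self.n_ramps)
        rise = active & (r < self.rise_s)
        u[rise] = r[rise] / self.rise_s
        plat = active & (r >= self.rise_s) & (r < self.rise_s + self.plateau_s)
        u[plat] = 1.0
        fall = active & (r >= self.rise_s + self.plateau_s)
        u[fall] = np.clip((self.ramp_duration_s - r[fall]) / self.fall_s, 0.0, 1.0)
        return float(u[0]) if scalar else u

    def current_mA(self, t):
        return self.i_max_mA * self.phase(t)

    def power_W(self, t, cal: CalibrationModel):
        return cal.power_W(self.current_mA(t), check_range=False)

    def p_max_W(self, cal: CalibrationModel) -> float:
        return float(cal.power_W(self.i_max_mA, check_range=False))

    # ---- windows ---------------------------------------------------------
    def ramp_window(self, i: int) -> tuple[float, float]:
        start = self.lead_in_s + i * self.ramp_duration_s
        return start, start + self.ramp_duration_s

    def plateau_window(self, i: int) -> tuple[float, float]:
        start = self.lead_in_s + i * self.ramp_duration_s + self.rise_s
        return start, start + self.plateau_s

    def matches(self, other: "LightProgram", rtol: float = 1e-3) -> bool:
        """Whether two programs agree in shape and amplitude within rtol."""
        pairs = [
            (self.rise_s, other.rise_s),
            (self.plateau_s, other.plateau_s),
            (self.fall_s, other.fall_s),
            (self.i_max_mA, other.i_max_mA),
            (self.lead_in_s, other.lead_in_s),
        ]
        if self.n_ramps != other.n_ramps:
            return False
        return all(abs(a - b) <= rtol * max(abs(a), abs(b), 1e-12) for a, b in pairs)

    @classmethod
    def from_power(cls, p_max_W: float, cal: CalibrationModel, **kwargs) -> "LightProgram":
        """Build a program whose plateau power equals ``p_max_W`` under ``cal``.

        Inverts the calibration numerically to find the plateau current.
        """
        if p_max_W <= 0:
            raise ValueError("plateau power must be positive")
        hi = cal.current_range_mA[1]
        while cal.power_W(2 * hi, check_range=False) < p_max_W:
            hi *= 2.0
        i_max = brentq(lambda i: cal.power_W(i, check_range=False) - p_max_W, 0.0, 2 * hi)
        return cls(i_max_mA=float(i_max), **kwargs)

    # meta round-trip for run-CSV headers
    def to_meta(self) -> dict:
        return {
            "program_rise_s": repr(self.rise_s),
            "program_plateau_s": repr(self.plateau_s),
            "program_fall_s": repr(self.fall_s),
            "program_n_ramps": repr(self.n_ramps),
            "program_lead_in_s": repr(self.lead_in_s),
            "program_tail_s": repr(self.tail_s),
            "program_i_max_mA": repr(self.i_max_mA),
            "program_sampling_s": repr(self.sampling_s),
        }

    @classmethod
    def from_meta(cls, meta: dict) -> "LightProgram | None":
        try:
            return cls(
                rise_s=float(meta["program_rise_s"]),
                plateau_s=float(meta["program_plateau_s"]),
                fall_s=float(meta["program_fall_s"]),
                n_ramps=int(meta["program_n_ramps"]),
                lead_in_s=float(meta["program_lead_in_s"]),
                tail_s=float(meta.get("program_tail_s", 0.0)),
                i_max_mA=float(meta["program_i_max_mA"]),
                sampling_s=float(meta.get("program_sampling_s", 1.0)),
            )
        except KeyError:
            return None
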