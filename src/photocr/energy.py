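"""Differential heat-flow reduction: live/dead pairing, PE and the error budget.

The calorimeter records the heat-flow difference between a measuring (M) and
a reference (R) vessel.  With photosynthetically inactive material on both
sides the differential ``ΔP_dead`` captures the optical/thermal imbalance of
the two arms; with active algae on the M side the differential ``ΔP_live``
additionally contains the photosynthetically conserved energy flow, so

    P_PS(t) = ΔP_live(t) − ΔP_dead(t)        (sign convention: conserving > 0)
    PE(t)   = P_PS(t) / P_I(t)               (masked where P_I is small)

The electrical polarity of the Peltier readout is absorbed into a per-trace
``sign`` flag (default +1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .optics import LightProgram


@dataclass
class HeatTrace:
    """A differential heat-flow time series on a uniform grid (W, s)."""

    time_s: np.ndarray
    power_W: np.ndarray
    role: str = "live"
    program: LightProgram | None = None
    baseline_offset_W: float = 0.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.power_W = np.asarray(self.power_W, dtype=float)
        if self.time_s.shape != self.power_W.shape:
            raise ValueError("time and power must have the same shape")
        if not np.all(np.isfinite(self.power_W)):
            raise ValueError("heat trace contains non-finite values")

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


def baseline_correct(trace: HeatTrace, window_s: float = 600.0) -> HeatTrace:
    """Subtract the mean of a dark pre-illumination window.

    The window is the last ``window_s`` seconds before light onset (the
    program lead-in if a program is attached, otherwise the first
    ``window_s`` seconds of the trace).  Raises if the trace does not cover
    the window.
    """
    if window_s <= 0:
        raise ValueError("baseline window must be positive")
    t_on = trace.program.lead_in_s if trace.program is not None else window_s
    mask = (trace.time_s >= t_on - window_s) & (trace.time_s < t_on)
    needed = int(round(window_s / trace.dt_s))
    if mask.sum() < max(2, needed // 2) or trace.time_s[0] > t_on - window_s + trace.dt_s:
        raise ValueError(
            f"insufficient pre-illumination data for a {window_s:g} s baseline window"
        )
    offset = float(trace.power_W[mask].mean())
    return replace(
        trace, power_W=trace.power_W - offset, baseline_offset_W=offset
    )


def conserved_power(
    live: HeatTrace, dead: HeatTrace, sign: int = +1
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise ``P_PS = sign·(ΔP_live − ΔP_dead)`` on the live trace's grid.

    Both traces must reference matching light programs (shape, amplitude and
    lead-in within tolerance); the dead trace is linearly interpolated onto
    the live grid.  Returns ``(time_s, p_ps_W)``.
    """
    if live.program is not None and dead.program is not None:
        if not live.program.matches(dead.program):
            raise ValueError("live and dead traces were recorded under different light programs")
    dead_on_live = np.interp(live.time_s, dead.time_s, dead.power_W)
    return live.time_s, sign * (live.power_W - dead_on_live)


def compute_pe(
    p_ps_W: np.ndarray,
    p_i_W: np.ndarray,
    threshold_W: float | None = None,
    threshold_frac: float = 0.05,
) -> np.ndarray:
    """``PE = P_PS/P_I`` where ``P_I`` exceeds the threshold, NaN elsewhere.

    The ratio is ill-conditioned as P_I -> 0; by default points below 5% of
    the maximum incident power are masked.
    """
    p_ps = np.asarray(p_ps_W, dtype=float)
    p_i = np.asarray(p_i_W, dtype=float)
    if threshold_W is None:
        threshold_W = threshold_frac * float(np.nanmax(p_i))
    ok = p_i > threshold_W
    pe = np.full_like(p_ps, np.nan)
    pe[ok] = p_ps[ok] / p_i[ok]
    return pe


def error_budget(sigma_live_W: float, signal_diff_W: float, delta_pi_rel: float = 0.0) -> float:
    """Maximum relative PE error: ``2·σ(ΔP_live)/(ΔP_live − ΔP_dead) + ΔP_I/P_I``.

    ``signal_diff_W`` is the live-minus-dead plateau signal; ``delta_pi_rel``
    the relative uncertainty of the light input.
    """
    if signal_diff_W <= 0:
        raise ValueError("signal difference must be positive")
    if sigma_live_W < 0 or delta_pi_rel < 0:
        raise ValueError("uncertainties must be non-negative")
    return 2.0 * sigma_live_W / signal_diff_W + delta_pi_rel


@dataclass
class PlateauStats:
    mean_W: float
    sd_W: float
    relative: float | None  # sd / P_I^Max
    n: int


def plateau_statistics(
    traces: list[HeatTrace],
    p_max_W: float | None = None,
    program: LightProgram | None = None,
    margin_s: float = 0.0,
) -> PlateauStats:
    """Pool plateau samples of one or more traces: mean, SD and SD/P_I^Max.

    ``program`` defaults to the first trace's program; it must contain a
    plateau segment.  ``margin_s`` trims the window edges.
    """
    if not traces:
        raise ValueError("need at least one trace")
    program = program or traces[0].program
    if program is None:
        raise ValueError("no light program available")
    if program.plateau_s <= 2 * margin_s:
        raise ValueError("light program has no usable plateau segment")
    samples = []
    for tr in traces:
        for i in range(program.n_ramps):
            lo, hi = program.plateau_window(i)
            m = (tr.time_s >= lo + margin_s) & (tr.time_s < hi - margin_s)
            samples.append(tr.power_W[m])
    pooled = np.concatenate(samples)
    if pooled.size == 0:
        raise ValueError("traces do not cover the plateau windows")
    sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    return PlateauStats(
        mean_W=float(pooled.mean()),
        sd_W=sd,
        relative=(sd / p_max_W) if p_max_W else None,
        n=int(pooled.size),
    )
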