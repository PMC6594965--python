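# Methods

## The measurement model

A differential isothermal calorimeter holds two identical closed 20 mL
ampoules (measuring M and reference R), each illuminated through one arm of
a split light guide driven by a blue LED (treated as monochromatic at
455 nm).  The instrument records the heat-flow difference between the two
sides at 1 Hz.  Two paired runs share one light program:

* **dead**: both sides photosynthetically inactive — the differential
  `ΔP_dead = imbalance · P_I` captures the slight optical asymmetry of the
  two arms;
* **live**: active algae on the M side — the differential additionally
  contains the conserved energy flow, `ΔP_live = ΔP_dead + P_PS`.

The reduction therefore forms `P_PS = ΔP_live − ΔP_dead` pointwise (after
interpolating both traces onto the light-program clock, with light onset
detected from the logged LED current channel) and the efficiency
`PE = P_PS/P_I`.  The electrical polarity of the Peltier readout is
absorbed into a per-trace `sign` flag (default +1), chosen so that active
photosynthesis gives positive `P_PS`.

Incident power comes from the optics calibration: a degree-3 polynomial,
constrained through the origin, maps drive current to radiation flow Φ
(µE s⁻¹); with three calibration triples the cubic is exactly determined.
`P_I = Φ·N_A·h·c/λ` (262.9 kJ per einstein at 455 nm).  Irradiance decay
with distance from the guide output follows the two-parameter exponential
`IR(δ) = IR₀ + A·(exp(B·δ) − 1)` with B < 0; the radiation flow relates to
the surface irradiance through the emitting area, `Φ = IR₀·(π/4)d²·1e-6`
(the area relation is dimensionally forced; a division by the area would
not carry the right units).

Oxygen: the liquid optode reads % air saturation, converted with a Henry
coefficient (`O_L = reading/100 · k_H·ξ_air·π`, default
k_H = 1.3·10⁻⁸ mol L⁻¹ Pa⁻¹ with 1.25·10⁻⁸ available as an explicit
argument, ξ_air = 0.2095); the headspace optode reads % volume fraction
(a % air-saturation dialect is selectable).  The closed vessel exchanges
O2 between phases at a first-order rate k_V, so the production rate is

    r_O2 = dO_L/dt + k_V·(O_L − k_H·ξ_O·π),

with k_V estimated from an algae-free run started with N2-purged liquid by
regressing dO_L/dt on the driving force (slope = −k_V; the intercept is a
diagnostic that should vanish).  A run that starts at equilibrium is
unidentifiable and is rejected.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| λ | 455 | nm | LED centre wavelength; spectral width not modelled |
| ramp rise / plateau / fall | 3600 / 1800 / 3600 | s | standard trapezoidal program |
| lead-in | 600 | s | dark baseline window before the first ramp |
| baseline window | 600 | s | residual offset SE = σ/√600 ≈ 1 µW at σ = 25 µW |
| PE threshold | 5% of P_I^Max | — | PE = P_PS/P_I is ill-conditioned as P_I → 0 |
| derivative smoothing | 301 s window, order 2 | — | 1 Hz sampling vs hour-scale dynamics; order 2 leaves a ≲0.3% curvature bias on exponentials (order 3 removes it, both configurable) |
| k_H | 1.3e-8 | mol L⁻¹ Pa⁻¹ | Henry coefficient under measurement conditions |
| k_V | 1.150e-3 | s⁻¹ | gas-exchange coefficient of the reference vessel |
| V_L, V_G | 10, 10 | mL | 20 mL ampoule with 10 g suspension |
| T, π | 293.15 K, 101325 Pa | | isothermal, isobaric operation |
| σ_heat | 25 | µW | plateau heat-flow noise of the reference instrument |
| σ_o2 | 0.1 | % of reading | typical optode noise; consistent with respirometry having slightly better SNR than the 0.13%-relative calorimetry |
| arm imbalance | 0.03 | — | puts the dead plateau near 590 µW at 19.6 mW input |
| oxycaloric equivalent | −455 | kJ mol⁻¹ | mean carbohydrate value used for scaling |
| v_max, k_m | 2.95e-6 mol g⁻¹ s⁻¹, 47.4 mW | | saturation of the specific O2 rate |
| µ | 0.071 | h⁻¹ | low-light specific growth rate |
| X₀ / CN₀ | 3.88e-4 g / 7.39e5 mL⁻¹ | | 52.5 pg per cell in 10 mL |

Regressions are ordinary least squares with intercept throughout; no
errors-in-variables correction is applied (a limitation — at the shipped
noise levels the regressor noise is ≪ its spread, so attenuation bias is
negligible, but this does not hold for arbitrarily noisy optodes).
Ratios of conserved energy to O2 are reported negative (enthalpy
convention).  Ramp maxima for the growth-rate estimate are taken from a
300 s moving mean, since raw maxima are dominated by the 25 µW noise; the
elapsed time between first and last maximum is `(n_ramps − 1)` ramp
periods, because the maxima of a growing culture recur at the same program
phase.

## The virtual instrument

The simulator runs the same physics forward:

* biomass `dX/dt = µ·X` while the light is on — growth is *prescribed*,
  not coupled to `P_PS` via a yield, so the ground truth stays analytic;
* volumetric O2 rate `r = v_max·P_I/(k_m+P_I)·(X/V_L)·C/(K_C+C)` (the
  carbon factor is 1 unless a pool is configured); conserved energy slaved
  to it through one true oxycaloric equivalent, `P_PS = |oxycal|·r·V_L`,
  which makes the energy balance hold identically;
* liquid/headspace exchange with an isobaric, ideal-gas headspace:
  `dξ/dt = V_L·k_V·(O_L − k_H·ξ·π)·R·T/(π·V_G)`;
* integration by fixed-step classical Runge–Kutta on the 1 s instrument
  clock (rates ≤ 1e-3 s⁻¹, nowhere near stiff).  RK4 preserves linear
  invariants, so total O2 moles minus the integrated production are
  conserved to machine precision — the mole-closure tests assert this
  directly, with the cumulative production carried as an extra state.
* channels: dead = `0.03·P_I + noise`, live = `0.03·P_I + P_PS + noise`
  (µW); optodes with multiplicative Gaussian noise; the LED current channel
  is written clean (its 8 mA ripple at 570 kHz is unresolvable at 1 Hz).

Identical seed and configuration give bit-identical output files.

**Carbon-limitation scenario.**  The dissolved-carbon deficiency experiment
is modelled once, as `carbon_limited_scenario()`: a 1.5 mM lumped pool
(15% of normal supplementation), K_C = 0.5 mM, a 61.1 mW three-ramp
program, and µ = 0.  Growth is disabled because in this forward model
biomass formation *is* carbon fixation — prescribing exponential growth
against a starving pool would be incoherent, and with µ = 0 the plateau
`P_PS` is strictly decreasing whenever the pool is consumed, so the
pre-plateau maximum and the declining ramp maxima are structural
consequences of depletion, not parameter accidents.  The pool is a single
lumped species: no CO2/bicarbonate speciation, pH or CCM kinetics.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: the calorimeter's thermal time constant (raw
ramp corners are sharp, real ones are smeared), optode drift and response
lag, self-shading and light-field inhomogeneity (the light response is
optically thin and linear in X by construction), photoinhibition beyond
saturation, dark respiration (default 0, configurable), Percoll effects on
solubility, and temperature/salinity dependence of the Henry coefficient.
Parameter-recovery results on simulated runs therefore demonstrate the
*reduction's* correctness and noise behaviour, not instrument accuracy.

## Numerical choices and degenerate inputs

* Savitzky–Golay endpoints use polynomial extrapolation within the edge
  windows (`mode="interp"`); the k_V regression trims half a window at
  each end to avoid edge artefacts.
* The distance-decay fit is initialised with IR₀ at the smallest distance,
  A from the observed drop and B = −3/span, with B bounded negative;
  non-convergence raises an error carrying the last iterate and residual.
* The through-origin cubic calibration is checked for monotonicity over
  the calibrated range (warning, not error); out-of-range currents warn
  and extrapolate, since ramps sweep the current continuously.
* `production_rate` with k_V = 0 degenerates to the raw smoothed
  derivative; a missing headspace channel is an error because the exchange
  correction is then undefined.
* Degenerate regressions (no spread in the regressor, too few points) and
  non-positive inputs to logarithmic/ratio formulas raise `ValueError`
  rather than returning NaN.

## Problem sizes

The shipped tests run the full-length five-ramp program (45 600 s at 1 Hz)
for the oxycaloric and growth-rate recoveries, 19 full-length replicates
for the reproducibility statistic, and a scaled-down trapezoid
(600/300/600 s, two ramps) for structural closed-loop checks; the whole
suite completes in a few seconds on one CPU.  Monte-Carlo examples use
30–100 seeds, enough to pin the quantile claims they assert.

## Known limitations

* OLS-with-intercept everywhere; see above.
* The error budget `2σ/ΔP + ΔP_I/P_I` is a worst-case linearised bound,
  not a distributional statement.
* The biomass molar mass uses 5-significant-digit atomic masses
  (C 12.011, H 1.008, O 15.999, N 14.007); the photon budget is computed
  with the unrounded molar mass of the configured composition.
* The saturation fit is only meaningful when the incident-power range
  brackets k_m; on low-light programs it extrapolates and its report
  entries should be ignored.
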