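# photocr

Photocalorespirometry (Photo-CR) data reduction and virtual-instrument
simulation.

Photo-CR measures the photosynthetic energy-conversion efficiency of a
microalgal suspension (e.g. *Chlamydomonas reinhardtii*) *directly*: a
differential isothermal calorimeter records the heat flow of an illuminated
closed vessel while oxygen optodes follow the dissolved and headspace O2.
Because the incident radiant power `P_I` is known from the LED calibration,
the photosynthetically conserved energy flow and the efficiency follow from
the energy balance

```
P_PS(t) = ΔP_heat_live(t) − ΔP_heat_dead(t)          PE(t) = P_PS(t) / P_I(t)
```

where the "dead" reference is the same suspension with metabolism blocked
(unchanged absorptivity), so purely optical/thermal asymmetries cancel.
The O2 production rate is recovered from the optode channels by correcting
for the first-order gas exchange of the closed ampoule,

```
r_O2 = dO_L/dt + k_V·(O_L − k_H·ξ_O·π)
```

and the ratio of the two observables — the calorespirometric (oxycaloric)
ratio, ≈ −430…−480 kJ per mol O2 for carbohydrate metabolism — flags side
reactions such as the Mehler water–water cycle.  Downstream the package
derives saturation ("Michaelis–Menten-like") light-response parameters,
specific growth rates from repeated trapezoidal light ramps, cell-specific
conserved power, biomass conversions and the photon budget of CO2 fixation.

Because no public raw Photo-CR data exist, the package ships a **virtual
instrument** (`photocr.simulate`) that generates paired live/dead runs with
known ground truth — trapezoidal light ramps, exponential growth,
Michaelis–Menten light response, liquid/headspace O2 exchange, Gaussian
heat-flow noise (σ ≈ 25 µW) — so every reduction stage is closed-loop
testable.

Intended users: biocalorimetry / photosynthesis-bioenergetics groups who
want a reference implementation of the reduction, and method developers who
need a simulator with exact energy and mole closures.

## Worked example

Simulate a five-ramp low-light run (plateau power 19.6 mW, growth rate
0.071 h⁻¹, true oxycaloric equivalent −455 kJ mol⁻¹) and reduce it:

```sh
photocr simulate --seed 7 --out-dir demo --p-max-mw 19.6 --ramps 5
photocr reduce --live demo/live.csv --dead demo/dead.csv --out-dir demo/reduced
photocr report --reduction demo/reduced/report.json
```

prints (abridged):

```
               key        value           se     units                         definition
         p_i_max_W       0.0196          NaN         W       P_I^Max = Phi(I_max)*N_A*E_P
pe_plateau_mean_R1     0.008606          NaN         -                      PE = P_PS/P_I
pe_plateau_mean_R5     0.017344          NaN         -                      PE = P_PS/P_I
    caloresp_ratio  -453.036702 9.172495e-01 kJ/mol O2         -slope of OLS P_PS vs R_O2
caloresp_pearson_r     0.921788          NaN         -
                mu     0.068644          NaN       1/h mu = ln(Xn/X1)/dt from ramp maxima
```

Reading the numbers: the plateau-mean efficiency rises from 0.86% to 1.7%
across the five ramps because the culture grows (more cells intercept the
same light); the fitted calorespirometric ratio −453.0 ± 0.9 kJ mol⁻¹
recovers the configured −455 within noise; and the growth rate estimated
from the ramp maxima, 0.069 h⁻¹, recovers the configured 0.071 h⁻¹.  The
saturation-fit entries of the report are only meaningful for high-light
programs whose power range brackets the half-saturation constant
(~43 mW) — on a 19.6 mW run they are extrapolations and should be ignored.

The same chain is available as library calls (`SimulationConfig`,
`simulate_run`, `reduce_run`), and `photocr simulate --exchange-only` plus
`photocr fit-kv` reproduce the algae-free gas-exchange calibration
(k_V ≈ 1.15·10⁻³ s⁻¹).

## Layout

```
src/photocr/optics.py        photon energetics, LED calibration, light programs
src/photocr/energy.py        heat-flow baselines, live/dead differencing, PE
src/photocr/gas_exchange.py  Henry conversion, k_V fit, corrected r_O2
src/photocr/derived.py       CR ratio, saturation fits, growth, photon budget
src/photocr/simulate.py      virtual instrument with exact closures
src/photocr/io.py, cli.py    run-CSV contract and the photocr command
docs/methods.md              model, assumptions, defaults, limitations
```
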