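# Methods

## The model

`thermodev` implements a carbon-balance account of how temperature shapes
biomass accumulation in wheat organs. Its premise is that two classes of
processes respond differently to temperature:

* **development** (leaf elongation, progress toward senescence or grain
  maturity) accelerates steeply with temperature up to an optimum near
  26.5 °C, responding to day and night temperature alike;
* **carbon exchange** — net photosynthesis responds weakly to (day)
  temperature, while dark respiration responds steeply to (night)
  temperature.

The net CO₂ assimilated *per unit of development* therefore falls as
temperature rises, and falls faster under night warming than day warming.
That single quantity, A_N.20°C, predicts biomass density in leaves (LMA)
and the rate of grain filling.

### Temperature-response function

Every rate process F(T) is modelled with a four-parameter enthalpy curve

    F(T) = A · T · exp(−ΔHA‡/(R·T)) / (1 + [exp(−ΔHA‡/(R·T))]^(α(1−T/T0)))

with T in Kelvin, R = 8.314 J mol⁻¹ K⁻¹ (the respiration rate is named
`r_night` throughout the package to avoid colliding with the gas
constant). ΔHA‡ (J mol⁻¹) sets the low-temperature curvature, α the
sharpness of the high-temperature collapse, T0 (K) the position of that
collapse, and A the trait scale. All interfaces use °C; Kelvin conversion
happens only inside the evaluation, which works in log space so that no
overflow occurs anywhere in (−50, 80) °C.

T0 is *not* the curve's argmax: with the development parameters
(ΔHA‡ = 69.1 kJ mol⁻¹, α = 3.5, T0 = 29.2 °C) the true maximum sits at
26.50 °C, verified against a 0.001 °C brute-force grid scan. The package
treats T0 strictly as a curve parameter and always computes optima
numerically (`find_optimum`, bounded scalar maximization, tolerance
0.01 °C, boundary-attained maxima flagged).

### Developmental time

One developmental day (d_20°C) is the development completed in one clock
day at constant 20 °C. A day under a day/night regime is worth

    f = [PP·F(T_day) + (24−PP)·F(T_night)] / (24·F(20 °C))

developmental days, with PP the photoperiod in hours. Day and night are
weighted separately (not through the 24-h mean temperature) because the
response curve is nonlinear and the experiments manipulate the two
independently. Rates divide by f, durations multiply by f, so
rate × time — accumulated biomass — is invariant under the change of
units. In treatment-replication modes the factor may be supplied directly
from measured leaf-elongation ratios instead of the fitted curve; the
fitted curve is the simulation default.

### Carbon balance

Daily photosynthesis and night respiration are constant-rate integrals of
instantaneous rates over the light and dark periods (12 h each by
default), and A_N = P_N − R_night; daytime respiration is implicitly part
of net photosynthesis. A_N.20°C = A_N / f.

### Senescence and grain filling

Chlorophyll (SPAD) time courses follow a plateau SPAD₀ until onset t_s,
then decline linearly with slope a_s. SPAD₀ is fixed across treatments to
the anthesis mean (57.3) by default. The breakpoint is profiled over a
0.1 d grid with the conditional linear fit in closed form, then polished
by bounded local optimization — the objective is non-smooth in t_s, and
grid+polish is deterministic and robust. The un-floored two-segment model
is used inside the least-squares objective; the zero floor in
`bilinear_value` is a physical clamp for prediction only.

Grain weight follows a logistic reparameterized so the anthesis weight
W₀ = 1.65 mg is itself a parameter:

    W(t) = W₀ (1 + e^{λt₀}) / (1 + e^{−λ(t−t₀)})

GGR_max = λW₀(1+e^{λt₀})/4 at the inflection t₀, invertible for λ by
bracketed root solving (tolerance 1e-12; round-trips to better than 1e-8),
and the filling duration is t_f = t₀ + ln(19)/λ (time to 95 % of final
weight, exact by construction). Spikes with fewer than 30 seeds are
excluded before fitting. Across treatments in developmental time, a
common t₀.20°C (default 20.2 d_20°C) is fitted in three stages: free
per-treatment fits, an inverse-variance-weighted mean of the t₀
estimates (equal weights if standard errors are unavailable), then
per-treatment λ refits with t₀ pinned. The weighting rule is this
package's choice of aggregator.

### Forward simulation

For each day of a scenario series (default 100 days from anthesis, 1 d
step): compute f, A_N, A_N.20°C, map A_N.20°C → λ_20°C through a linear
link fitted on treatment data, evaluate the logistic growth-rate kernel at
the running developmental time with that day's λ_20°C and fixed
(W₀, t₀.20°C), and advance the weight. The printed integral form is read
as W(t) = W₀ + ∫₀^{t_20} GGR_20 dx, since W(0) must equal W₀. λ_20°C is
applied instantaneously with no smoothing or memory, and day/night
transitions are instantaneous. Quadrature is midpoint rectangles (one
kernel evaluation per step): left-endpoint rectangles at a 1 d step miss
the ≤1 % agreement with the closed-form constant-scenario logistic
whenever f > 1 (measured 1.5 % at 23/18 °C), while the midpoint rule is
O(h²) and stays well inside 1 % at 1 d and 0.1 % with 10× sub-stepping.
Under any constant scenario the simulation is exactly a time-rescaled
logistic; the tests use this closed form as the oracle. The reported
filling duration is the first day reaching 95 % of the end-of-series
weight (the trajectory's plateau; with a time-varying λ there is no single
closed-form asymptote).

Literature comparisons (`evaluate_against_table`) consume a user-supplied
CSV of paired thermal scenarios with observed final-weight reductions;
reported R² is the squared Pearson correlation of predicted vs observed,
and bias is the mean signed relative error 100·mean((pred − obs)/obs) over
rows with a non-zero observation.

## Parameters and defaults

| parameter | default | units | status |
|---|---|---|---|
| ΔHA‡ (development/LER) | 69.1e3 | J mol⁻¹ | measured |
| α (development) | 3.5 | – | convention |
| T0 (development) | 302.35 | K | measured |
| ΔHA‡ (P_N, growth light) | 19.3e3 | J mol⁻¹ | measured |
| ΔHA‡ (P_N, saturating light) | 36.2e3 | J mol⁻¹ | measured, optional |
| ΔHA‡ (R_night) | 74.9e3 | J mol⁻¹ | measured |
| T0, α, amplitude (P_N) | 310 K, 2.5, 26 µmol m⁻² s⁻¹ at 20 °C | | calibration default |
| T0, α, amplitude (R_night) | 318 K, 3.5, 1.56 µmol m⁻² s⁻¹ at 20 °C | | calibration default |
| link λ_20 = a·A_N.20 + b | a = 0.034, b = 0.105 | | calibration default |
| SPAD₀ | 57.3 | SPAD | fixed plateau |
| W₀ | 1.65 | mg | fixed anthesis weight |
| t₀.20°C | 20.2 | d_20°C | common inflection |

"Calibration default" marks values the source measurements do not pin
down; they were chosen once so the system reproduces the documented
qualitative behaviour (A_N.20°C ≈ 1.3 mol m⁻² d_20°C⁻¹ at 20/15 °C,
declining with temperature; respiration steeply night-responsive;
night-warming weight losses in the 10–20 % range) and are clearly
labelled in `gas_exchange.py` and `simulator.default_link`. They are not
measured values and analyses of real data should refit them.

Fitting conventions: response-curve fits run multi-start (10 seeded
starts) trust-region least squares with A parameterized on a log scale —
A balances an Arrhenius factor of order 1e-13 and spans many orders of
magnitude — with bounds ΔHA‡ ∈ [1, 400] kJ mol⁻¹, T0 ∈ [273.15, 333.15] K,
α ∈ [0.5, 20] when free (fixed at 3.5 for development-class processes).
Goodness of fit is R² on the untransformed rate scale. Fits consume raw
replicates, not replicate means. Maturity samplings carry the same weight
as interim samplings (no heteroscedasticity modelling).

## The synthetic data generator

`synthetic_data` emulates the three study designs from known truths: five
constant temperatures (11–29 °C, n = 8 elongation / n = 4 gas exchange),
four day/night regimes (20/15, 20/20, 25/15, 25/20 °C, n = 6), and
post-anthesis SPAD (9 sampling days, 4 plants) and grain-weight courses
(5 sampling days plus maturity at 55 d_20°C, 4 spikes) with seed counts,
a configurable fraction (default 10 %) drawn below the 30-seed exclusion
threshold. Truths are internally consistent: a common t_s.20°C
(22.5 d_20°C) and t₀.20°C (20.2 d_20°C) across treatments, per-treatment
clock values derived through each regime's dev factor, per-treatment
λ_20°C through the link, and LMA linear in A_N.20°C (slope 25 g m⁻² per
unit, intercept 15 g m⁻²).

Noise is Gaussian — 5 % multiplicative on elongation, gas-exchange and
grain-weight values, additive SD 2 SPAD, additive SD 1.5 g m⁻² on LMA —
sized so fits on default data reach the goodness levels reported for
low-noise real measurements (R² ≥ 0.97 for curve fits and the LMA and
link correlations). Generation is deterministic per seed.

What the generator does **not** emulate: between-plant random effects
(noise is i.i.d. per observation), photosynthetic/respiratory acclimation,
carbon remobilization to the grain, VPD effects, sub-daily temperature
profiles, or genotypic variability. Passing tests therefore demonstrate
that the estimation machinery recovers known truths under the stated
noise model — not that the model captures every source of variation in
real field or chamber data.

## Numerical choices

* Curve evaluation in log space; `logaddexp` for the denominator.
* `find_optimum`: bounded Brent search on [0 °C, T0 − 273.15 + 15 °C],
  tolerance 0.01 °C; agrees with a 0.001 °C grid scan within 0.02 °C.
* Bilinear breakpoint: 0.1 d grid + bounded polish; degenerate series
  (no detectable decline, fewer than two post-onset points) raise a named
  error.
* λ inversion: Brent bracketed on (0, 2] d⁻¹ with explicit out-of-range
  error when the bracket has no sign change.
* Bootstrap: case-resampling percentile intervals, 2.5/97.5 %,
  deterministic per seed; degenerate refits dropped and counted, >20 %
  drop warns. The default resampling unit is the single observation. With
  only four plants, resampling whole plants admits just 35 distinct
  resamples and its intervals undercover materially (≈80 % at nominal
  95 % in a 100-simulation study, against an estimator SD that
  observation-level intervals match, covering at 92–94 %); plant-level
  resampling remains available (`unit="plant"`) for data with real
  plant-level effects.
* Simulation: midpoint rectangles, 1 d default step, optional
  sub-stepping; halving the step moves the final weight by < 0.5 %.

## Problem sizes

Monte-Carlo studies in the tests and the acceptance script use 100 seeds
for the curve-fit and senescence recovery studies, 15 seeds for the
shared-t₀ study, and 300 outer simulations × 199 bootstrap replicates for
the coverage study — sizes at which the medians and the coverage
proportion are stable to well within the tolerances asserted.

## Known limitations

* P_N/R amplitudes, their T0s and the link coefficients are calibration
  defaults (see above); simulated absolute weights and reduction
  percentages inherit that uncertainty, and only their signs, orderings
  and broad magnitudes are asserted.
* A_N.20°C is not monotone in temperature immediately above the
  development optimum (~26.5 °C): the dev factor declines faster there
  than A_N, so the ratio turns upward. The monotone-decline property is
  asserted at the five measured constant temperatures (11, 17, 20, 23,
  29 °C), which is what the source data resolve.
* The bilinear and logistic fits assume i.i.d. Gaussian errors; no
  autocorrelation within a plant's time course is modelled.
* The λ_20°C link is linear and memory-free; acclimation would bend or
  shift it over sustained exposure.
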