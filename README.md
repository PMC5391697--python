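# thermodev

Thermal-response modelling of wheat development, carbon assimilation and
grain growth.

Rising temperature speeds up everything a wheat plant does — but not
equally. Developmental processes (leaf elongation, progress toward
senescence and grain maturity) accelerate steeply up to an optimum near
26.5 °C and respond to day and night temperature alike; net photosynthesis
responds weakly to day temperature, while dark respiration responds
steeply to night temperature. The net carbon assimilated *per unit of
development*, written A_N.20°C, therefore falls as temperature rises —
and falls harder under night warming. This single quantity predicts leaf
mass per area and the rate of grain filling, and lets one simulate final
grain weight under arbitrary day/night temperature scenarios.

`thermodev` is for crop physiologists and modellers who want that chain
as a tested library: curve fitting, unit conversion, senescence and
grain-filling regressions, and forward simulation, plus a synthetic-data
generator that reproduces the statistical structure of the underlying
three-experiment design so every stage can be exercised without raw
measurements.

## The model in brief

Each rate process follows the enthalpy-based response

F(T) = A·T·e^(−ΔHA‡/RT) / (1 + [e^(−ΔHA‡/RT)]^(α(1−T/T₀))),

with ΔHA‡ = 69.1 kJ mol⁻¹ (development), 19.3 (net photosynthesis) and
74.9 (dark respiration). A day under a regime with photoperiod PP and
temperatures T_day/T_night is worth
f = [PP·F(T_day) + (24−PP)·F(T_night)]/(24·F(20 °C)) developmental days
(d_20°C); rates divide by f and durations multiply by f. Daily net
assimilation is A_N = P_N − R_night, and A_N.20°C = A_N/f.

Senescence is a bilinear SPAD decline (plateau SPAD₀ = 57.3 until onset
t_s, then slope a_s); grain weight is a constrained logistic
W(t) = W₀(1+e^{λt₀})/(1+e^{−λ(t−t₀)}) with W₀ = 1.65 mg, a common
inflection t₀.20°C = 20.2 d_20°C across treatments, and maximum growth
rate GGR_max = λW₀(1+e^{λt₀})/4. A linear link λ_20°C = a·A_N.20°C + b
closes the loop, and grain weight under any scenario is the integral of
the logistic growth-rate kernel in developmental time.

## Worked example

```python
import thermodev as td

# fit the development response to constant-temperature elongation data
data = td.gen_exp1(td.GeneratorConfig(), seed=42)
fit = td.fit_response(data["ler"][["temperature_C", "rate"]].to_numpy(),
                      fix_alpha=td.ALPHA_DEVELOPMENT, seed=0)
opt = td.find_optimum(fit.params)

# one day at 25/20 °C in developmental units
f = td.scenario_dev_factor(fit.params, td.ThermalScenario(t_day=25, t_night=20))

# grain filling at the observed maximum growth rate
lam = td.lambda_from_ggrmax(1.18)
p = td.GrainGrowthParams(w0=1.65, t0=20.2, lam=lam, time_basis="developmental")

# night warming: 20/15 °C vs 20/20 °C
cfg = td.GeneratorConfig()
base = td.simulate_grain(
    td.build_series({"days": 100, "t_day_C": 20, "t_night_C": 15}),
    cfg.dev_params, cfg.pn_params, cfg.r_params, cfg.link)
warm = td.simulate_grain(
    td.build_series({"days": 100, "t_day_C": 20, "t_night_C": 20}),
    cfg.dev_params, cfg.pn_params, cfg.r_params, cfg.link)
```

prints (via the obvious `print` statements):

```
dHa = 69.0 kJ/mol, T0 = 29.2 C, R2 = 0.987
development optimum = 26.5 C
25/20 C dev factor = 1.181 d20 per day
lambda = 0.1450 /d20, filling duration = 40.5 d20
final grain weight 20/15 C: 36.1 mg
final grain weight 20/20 C: 30.1 mg
night-warming reduction: 16.6 %
```

Reading this: the fitted development curve recovers its generating
enthalpy and peaks at 26.5 °C; a 25/20 °C day advances development 1.18×
faster than a 20 °C day; a grain filling at GGR_max.20°C =
1.18 mg d_20°C⁻¹ takes 40.5 developmental days to reach 95 % of its final
weight; and warming nights by 5 °C at constant day temperature cuts
simulated final grain weight by 16.6 % — night warming costs more than
the same warming applied by day (11.2 %), because respiration's
temperature response is far steeper than photosynthesis's while
development accelerates either way.

The same steps are available from the shell:

```sh
thermodev synth --experiment 1 --seed 42 --out data/
thermodev fit-response --csv data/exp1_ler.csv --fix-alpha 3.5
thermodev pipeline --out run/ --seed 1        # the whole chain
```

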