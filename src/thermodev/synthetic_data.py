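"""Synthetic datasets with the statistical structure of the three
experiments the framework is built around.

* Experiment 1: leaf elongation rate (LER) and instantaneous gas exchange
  at five constant temperatures (11, 17, 20, 23, 29 °C); n = 8 plants for
  LER, n = 4 for gas exchange.
* Experiment 2: LER, gas exchange and leaf mass per area (LMA) under four
  day/night regimes (20/15, 20/20, 25/15, 25/20 °C); n = 6.
* Experiment 3: SPAD chlorophyll time courses (days 0, 7, 13, 19, 25, 31,
  38, 42, 46 after anthesis; 4 plants) and single-grain dry weight time
  courses (days 7, 13, 19, 25, 31 + maturity; 4 spikes) under the same
  four regimes, with spike seed counts so the < 30-seed exclusion filter
  can be exercised.

All values are drawn from known true parameters: response curves for
development, photosynthesis and respiration; a common senescence onset and
a common grain inflection in developmental time; per-treatment logistic
slopes derived from the A_N.20°C → λ_20°C link.  Noise defaults (5 %
multiplicative on rates and weights, additive SD 2 on SPAD) are sized so
fits on default data reach the goodness levels seen on low-noise real
measurements; they are declared choices, not estimates of the real
replicate variance.  Generation is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .devtime import ThermalScenario, scenario_dev_factor
from .gas_exchange import an_response, default_pn_params, default_r_params
from .grain_growth import GrainGrowthParams, T0_20_DEFAULT, W0_DEFAULT, weight_at
from .senescence import SPAD0_DEFAULT, SenescenceParams, bilinear_value
from .simulator import AssimilationLink, default_link
from .thermal_response import ALPHA_DEVELOPMENT, ResponseParams, response_rate

__all__ = ["GeneratorConfig", "default_dev_params", "gen_exp1", "gen_exp2",
           "gen_exp3", "TREATMENTS"]

#: The four day/night regimes (t_day, t_night) in °C.
TREATMENTS = ((20.0, 15.0), (20.0, 20.0), (25.0, 15.0), (25.0, 20.0))


def default_dev_params() -> ResponseParams:
    """True development (LER) response: measured dHa, alpha and T0, with
    the amplitude scaled to 3 mm h⁻¹ at 20 °C (a typical wheat leaf-6
    elongation rate)."""
    base = ResponseParams(A=1.0, dHa=69.1e3, alpha=ALPHA_DEVELOPMENT,
                          T0=29.2 + 273.15)
    return base.scaled_to(3.0, 20.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """True parameters, designs and noise levels for the generators."""

    dev_params: ResponseParams = field(default_factory=default_dev_params)
    pn_params: ResponseParams = field(default_factory=default_pn_params)
    r_params: ResponseParams = field(default_factory=default_r_params)
    link: AssimilationLink = field(default_factory=default_link)

    # senescence truth, shared across treatments in developmental time
    spad0: float = SPAD0_DEFAULT
    ts_20: float = 22.5           # d_20°C
    as_20: float = -1.4           # SPAD per d_20°C

    # grain truth
    w0: float = W0_DEFAULT        # mg
    t0_20: float = T0_20_DEFAULT  # d_20°C
    maturity_20: float = 55.0     # d_20°C of the maturity sampling

    # designs
    exp1_temperatures: tuple = (11.0, 17.0, 20.0, 23.0, 29.0)
    treatments: tuple = TREATMENTS
    photoperiod: float = 12.0
    n_ler_exp1: int = 8
    n_gas_exp1: int = 4
    n_exp2: int = 6
    n_plants_exp3: int = 4
    spad_schedule: tuple = (0.0, 7.0, 13.0, 19.0, 25.0, 31.0, 38.0, 42.0, 46.0)
    grain_schedule: tuple = (7.0, 13.0, 19.0, 25.0, 31.0)

    # noise model
    ler_cv: float = 0.05          # multiplicative
    gas_cv: float = 0.05          # multiplicative
    spad_sd: float = 2.0          # additive, SPAD units
    grain_cv: float = 0.05        # multiplicative
    lma_sd: float = 1.5           # additive, g m⁻²

    # LMA truth: linear in A_N.20°C
    lma_slope: float = 25.0       # g m⁻² per (mol m⁻² d_20°C⁻¹)
    lma_intercept: float = 15.0   # g m⁻²

    # seed-count model for the >= 30-seed filter
    low_seed_fraction: float = 0.1

    def scenario(self, t_day: float, t_night: float) -> ThermalScenario:
        return ThermalScenario(t_day=t_day, t_night=t_night,
                               photoperiod=self.photoperiod)

    def treatment_truth(self, t_day: float, t_night: float) -> dict:
        """Per-treatment derived truths: dev factor, A_N, A_N.20, λ_20."""
        scen = self.scenario(t_day, t_night)
        f = scenario_dev_factor(self.dev_params, scen)
        a_n = an_response(self.pn_params, self.r_params, scen).a_n
        a_n_20 = a_n / f
        return {"factor": f, "a_n": a_n, "a_n_20": a_n_20,
                "lambda_20": self.link.predict(a_n_20)}


def _mult_noise(rng: np.random.Generator, values: np.ndarray, cv: float):
    noisy = values * (1.0 + cv * rng.standard_normal(values.shape))
    return np.maximum(noisy, 1e-9)


def _treatment_label(t_day: float, t_night: float) -> str:
    return f"{t_day:g}/{t_night:g}"


def gen_exp1(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> dict:
    """Constant-temperature LER and gas-exchange tables.

    Returns ``{"ler": DataFrame, "gas": DataFrame}`` with the module CSV
    schemas (``temperature_C, rate, replicate`` and ``treatment, t_day_C,
    t_night_C, photosynthesis_umol_m2_s, respiration_umol_m2_s,
    replicate``).
    """
    rng = np.random.default_rng(seed)
    ler_rows, gas_rows = [], []
    for temp in config.exp1_temperatures:
        true_ler = response_rate(config.dev_params, temp)
        rates = _mult_noise(rng, np.full(config.n_ler_exp1, true_ler),
                            config.ler_cv)
        for rep, r in enumerate(rates, 1):
            ler_rows.append({"temperature_C": temp, "rate": r, "replicate": rep})
        true_pn = response_rate(config.pn_params, temp)
        true_r = response_rate(config.r_params, temp)
        pns = _mult_noise(rng, np.full(config.n_gas_exp1, true_pn), config.gas_cv)
        rs = _mult_noise(rng, np.full(config.n_gas_exp1, true_r), config.gas_cv)
        for rep, (p, r) in enumerate(zip(pns, rs), 1):
            gas_rows.append({"treatment": f"{temp:g}C", "t_day_C": temp,
                             "t_night_C": temp, "photosynthesis_umol_m2_s": p,
                             "respiration_umol_m2_s": r, "replicate": rep})
    return {"ler": pd.DataFrame(ler_rows), "gas": pd.DataFrame(gas_rows)}


def gen_exp2(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> dict:
    """Day/night-regime LER, gas-exchange and LMA tables.

    LER integrates the development response over the photoperiod-weighted
    day (so night-only contrasts change LER but barely change A_N); LMA is
    linear in the true A_N.20°C, so the pipeline's LMA correlation has a
    known ground truth (perfectly collinear in the noiseless limit).
    """
    rng = np.random.default_rng(seed)
    ler_rows, gas_rows, lma_rows = [], [], []
    ler20 = response_rate(config.dev_params, 20.0)
    for t_day, t_night in config.treatments:
        label = _treatment_label(t_day, t_night)
        truth = config.treatment_truth(t_day, t_night)
        true_ler = ler20 * truth["factor"]  # 24-h mean elongation rate
        rates = _mult_noise(rng, np.full(config.n_exp2, true_ler), config.ler_cv)
        for rep, r in enumerate(rates, 1):
            ler_rows.append({"treatment": label, "t_day_C": t_day,
                             "t_night_C": t_night, "rate": r, "replicate": rep})
        true_pn = response_rate(config.pn_params, t_day)
        true_r = response_rate(config.r_params, t_night)
        pns = _mult_noise(rng, np.full(config.n_exp2, true_pn), config.gas_cv)
        rs = _mult_noise(rng, np.full(config.n_exp2, true_r), config.gas_cv)
        for rep, (p, r) in enumerate(zip(pns, rs), 1):
            gas_rows.append({"treatment": label, "t_day_C": t_day,
                             "t_night_C": t_night,
                             "photosynthesis_umol_m2_s": p,
                             "respiration_umol_m2_s": r, "replicate": rep})
        true_lma = config.lma_slope * truth["a_n_20"] + config.lma_intercept
        lmas = true_lma + config.lma_sd * rng.standard_normal(config.n_exp2)
        for rep, v in enumerate(lmas, 1):
            lma_rows.append({"treatment": label, "t_day_C": t_day,
                             "t_night_C": t_night, "lma_g_m2": v,
                             "replicate": rep})
    return {"ler": pd.DataFrame(ler_rows), "gas": pd.DataFrame(gas_rows),
            "lma": pd.DataFrame(lma_rows)}


def gen_exp3(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> dict:
    """Post-anthesis SPAD and grain-weight time courses under the four
    regimes, plus spike seed counts.

    The truth shares SPAD_0, t_s.20°C and t_0.20°C across treatments; each
    treatment's clock-time parameters follow from its dev factor, and its
    λ_20°C from the A_N.20°C link — so the analysis pipeline has exact
    ground truth to recover.  A ``low_seed_fraction`` of spikes draws a
    seed count below 30 to exercise the exclusion filter.
    """
    rng = np.random.default_rng(seed)
    spad_rows, grain_rows = [], []
    for t_day, t_night in config.treatments:
        label = _treatment_label(t_day, t_night)
        truth = config.treatment_truth(t_day, t_night)
        f = truth["factor"]
        sen = SenescenceParams(spad0=config.spad0, t_s=config.ts_20 / f,
                               a_s=config.as_20 * f)
        for plant in range(1, config.n_plants_exp3 + 1):
            for day in config.spad_schedule:
                val = bilinear_value(sen, day) + config.spad_sd * rng.standard_normal()
                spad_rows.append({"treatment": label, "plant_id": f"{label}-p{plant}",
                                  "days_after_anthesis": day,
                                  "spad": max(val, 0.0)})
        grain = GrainGrowthParams(w0=config.w0, t0=config.t0_20 / f,
                                  lam=truth["lambda_20"] * f, time_basis="clock")
        maturity_day = float(np.ceil(config.maturity_20 / f))
        days = list(config.grain_schedule) + [maturity_day]
        for spike in range(1, config.n_plants_exp3 + 1):
            low = rng.random() < config.low_seed_fraction
            seed_count = int(rng.integers(15, 30) if low else rng.integers(35, 55))
            for day in days:
                w = float(_mult_noise(rng, np.asarray(weight_at(grain, day)),
                                      config.grain_cv))
                grain_rows.append({"treatment": label,
                                   "spike_id": f"{label}-s{spike}",
                                   "days_after_anthesis": day,
                                   "grain_weight_mg": w,
                                   "seed_count": seed_count,
                                   "is_maturity": day == maturity_day})
    return {"spad": pd.DataFrame(spad_rows), "grain": pd.DataFrame(grain_rows)}
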