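"""Daily carbon balance from instantaneous gas-exchange rates.

Daily net photosynthesis P_N (light period) and night respiration R_night
(dark period) are constant-rate integrals of instantaneous rates measured
in µmol CO₂ m⁻² s⁻¹, and the daily net assimilation is their balance,
``A_N = P_N − R_night`` (mol m⁻² d⁻¹).  Daytime respiration is implicitly
inside net photosynthesis and is not modelled separately.

Dividing A_N by a day's developmental-time factor gives A_N.20°C, the
carbon assimilated per standard unit of plant development — the quantity
that links thermal regime to biomass accumulation in leaves and grains.

The module ships default P_N and R_night response curves whose enthalpies
of activation are the measured 19.3 and 74.9 kJ mol⁻¹; their T0 and
amplitudes are calibration defaults chosen to satisfy the qualitative
behaviour of the system (P_N rises with day temperature below its optimum,
R_night rises steeply with night temperature, A_N.20°C declines as
constant temperature rises), not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .devtime import ThermalScenario, compensate_rate
from .thermal_response import ResponseParams, response_rate

__all__ = [
    "DailyGasExchange",
    "daily_integral",
    "net_assimilation",
    "an_response",
    "an_20",
    "default_pn_params",
    "default_r_params",
    "DHA_PN",
    "DHA_PN_SATURATING",
    "DHA_R",
]

#: Enthalpy of activation of daily net photosynthesis at growth light, J mol⁻¹.
DHA_PN = 19.3e3
#: Enthalpy of activation of photosynthesis under saturating light, J mol⁻¹.
DHA_PN_SATURATING = 36.2e3
#: Enthalpy of activation of night respiration, J mol⁻¹.
DHA_R = 74.9e3

# Calibration defaults (T0, alpha, 20 °C amplitude) — not measured values.
_PN_T0_K = 310.0
_PN_ALPHA = 2.5
_PN_RATE_20C = 26.0  # µmol m⁻² s⁻¹
_R_T0_K = 318.0
_R_ALPHA = 3.5
_R_RATE_20C = 1.56  # µmol m⁻² s⁻¹


def default_pn_params(*, saturating_light: bool = False) -> ResponseParams:
    """Default net-photosynthesis response curve.

    The enthalpy of activation is the measured value (19.3 kJ mol⁻¹ at
    growth light; 36.2 kJ mol⁻¹ with ``saturating_light=True``); T0, alpha
    and the amplitude are calibration defaults.
    """
    dha = DHA_PN_SATURATING if saturating_light else DHA_PN
    base = ResponseParams(A=1.0, dHa=dha, alpha=_PN_ALPHA, T0=_PN_T0_K)
    return base.scaled_to(_PN_RATE_20C, 20.0)


def default_r_params() -> ResponseParams:
    """Default night-respiration response curve (measured dHa = 74.9 kJ mol⁻¹;
    T0, alpha and amplitude are calibration defaults)."""
    base = ResponseParams(A=1.0, dHa=DHA_R, alpha=_R_ALPHA, T0=_R_T0_K)
    return base.scaled_to(_R_RATE_20C, 20.0)


@dataclass(frozen=True)
class DailyGasExchange:
    """Daily carbon balance of one leaf/treatment.

    ``a_n`` is stored as exactly ``p_n − r_night``; a negative balance is
    flagged, not rejected (a dark-dominated day can respire more than it
    assimilates).
    """

    p_n: float
    r_night: float
    a_n: float
    negative_balance: bool = False

    def __post_init__(self) -> None:
        if self.p_n < 0 or self.r_night < 0:
            raise ValueError("p_n and r_night must be >= 0")
        if self.a_n != self.p_n - self.r_night:
            raise ValueError("a_n must equal p_n - r_night exactly")


def daily_integral(instantaneous_rate: float, hours: float) -> float:
    """Integrate a constant instantaneous rate (µmol m⁻² s⁻¹) over part of a
    day (hours in [0, 24]) to a daily total in mol m⁻² d⁻¹."""
    if not np.isfinite(instantaneous_rate):
        raise ValueError("rate must be finite")
    if not (0.0 <= hours <= 24.0):
        raise ValueError(f"hours must be in [0, 24], got {hours}")
    return instantaneous_rate * 3600.0 * hours * 1e-6


def net_assimilation(p_n: float, r_night: float) -> DailyGasExchange:
    """Daily net CO₂ assimilation A_N = P_N − R_night (mol m⁻² d⁻¹)."""
    a_n = p_n - r_night
    return DailyGasExchange(p_n=p_n, r_night=r_night, a_n=a_n,
                            negative_balance=a_n < 0)


def an_response(pn_params: ResponseParams, r_params: ResponseParams,
                scenario: ThermalScenario) -> DailyGasExchange:
    """Daily carbon balance implied by response curves under a scenario.

    Photosynthesis runs at F_PN(T_day) through the photoperiod and
    respiration at F_R(T_night) through the dark period, each integrated as
    a constant rate.
    """
    p_n = daily_integral(response_rate(pn_params, scenario.t_day),
                         scenario.photoperiod)
    r = daily_integral(response_rate(r_params, scenario.t_night),
                       24.0 - scenario.photoperiod)
    return net_assimilation(p_n, r)


def an_20(a_n: float, dev_factor: float) -> float:
    """A_N per unit of developmental time (mol m⁻² d_20°C⁻¹)."""
    return compensate_rate(a_n, dev_factor)
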