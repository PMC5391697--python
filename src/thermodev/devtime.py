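"""Developmental-time (thermal-time) compensation of rates and durations.

One unit of developmental time, d_20°C, is the amount of development a
plant completes in one day at a constant 20 °C.  A day spent at another
temperature is worth ``f = F(T)/F(20 °C)`` developmental days, where F is
the development response curve (leaf elongation is the conventional proxy,
its normalized response standing for all developmental processes).

Rates and times transform reciprocally:

* rate per clock day  →  rate per d_20°C:   ``J_20 = J / f``
* clock duration      →  d_20°C duration:   ``t_20 = t × f``

so the product rate × time — biomass accumulated — is invariant.

A day/night thermal scenario contributes its photoperiod-weighted factor
``f = [PP·f(T_day) + (24−PP)·f(T_night)] / 24``; day and night fractions
are weighted separately rather than through a 24-h mean temperature,
because the response curve is non-linear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .thermal_response import ResponseParams, normalized_response

__all__ = [
    "ThermalScenario",
    "scenario_dev_factor",
    "compensate_rate",
    "compensate_time",
    "accumulate_devtime",
]


@dataclass(frozen=True)
class ThermalScenario:
    """One day/night temperature regime.

    Attributes
    ----------
    t_day, t_night : float
        Day and night air temperatures, °C; must lie in (−20, 50).
    photoperiod : float
        Hours of light per 24 h, in [0, 24].  Default 12 h.
    """

    t_day: float
    t_night: float
    photoperiod: float = 12.0

    def __post_init__(self) -> None:
        for name, t in (("t_day", self.t_day), ("t_night", self.t_night)):
            if not (np.isfinite(t) and -20.0 < t < 50.0):
                raise ValueError(f"{name} must be in (-20, 50) °C, got {t}")
        if not (np.isfinite(self.photoperiod) and 0.0 <= self.photoperiod <= 24.0):
            raise ValueError(f"photoperiod must be in [0, 24] h, got {self.photoperiod}")

    @property
    def t_ave(self) -> float:
        """Photoperiod-weighted 24-h mean temperature, °C."""
        pp = self.photoperiod
        return (pp * self.t_day + (24.0 - pp) * self.t_night) / 24.0


def scenario_dev_factor(dev_params: ResponseParams, scenario: ThermalScenario,
                        reference: float = 20.0) -> float:
    """Developmental-time factor of one day under a day/night scenario.

    Photoperiod-weighted mean of the normalized development response at the
    day and night temperatures; equals 1 for a 20/20 °C regime.
    """
    pp = scenario.photoperiod
    f_day = normalized_response(dev_params, scenario.t_day, reference)
    f_night = normalized_response(dev_params, scenario.t_night, reference)
    return (pp * f_day + (24.0 - pp) * f_night) / 24.0


def _check_factor(factor: float) -> float:
    f = float(factor)
    if not (np.isfinite(f) and f > 0):
        raise ValueError(f"dev factor must be finite and > 0, got {factor}")
    return f


def compensate_rate(rate: float, factor: float) -> float:
    """Equivalent rate at 20 °C: trait units per d_20°C (divide by the factor)."""
    return rate / _check_factor(factor)


def compensate_time(duration: float, factor: float) -> float:
    """Clock duration re-expressed in d_20°C (multiply by the factor)."""
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    return duration * _check_factor(factor)


def accumulate_devtime(series: Sequence[ThermalScenario] | Iterable[ThermalScenario],
                       dev_params: ResponseParams) -> np.ndarray:
    """Cumulative developmental time over a per-day scenario series.

    Element ``i`` is the d_20°C elapsed through the end of day ``i`` (days
    are 1 d long; anthesis/treatment start is t = 0 with 0 d_20°C elapsed).
    Monotone non-decreasing; same length as the series.
    """
    series = list(series)
    if not series:
        raise ValueError("scenario series must be non-empty")
    factors = [scenario_dev_factor(dev_params, s) for s in series]
    return np.cumsum(factors)
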