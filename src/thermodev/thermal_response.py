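"""Enthalpy-based temperature-response curves for plant rate processes.

The rate of a biological process (leaf elongation, photosynthesis,
respiration ...) as a function of temperature ``T`` (Kelvin) is modelled as

.. math::

    F(T) = \\frac{A\\,T\\,e^{-\\Delta H_A/(R T)}}
                {1 + \\left[e^{-\\Delta H_A/(R T)}\\right]^{\\alpha(1 - T/T_0)}}

where ``dHa`` (J mol⁻¹) is the enthalpy of activation controlling the
low-temperature curvature, ``alpha`` (dimensionless) sets how sharply the
rate collapses above the optimum, ``T0`` (K) positions the high-temperature
decline, and ``A`` scales the curve to the trait's units.  All public
interfaces take temperatures in °C; the Kelvin conversion happens only
inside the evaluation.

Development-class processes (leaf elongation and, by extension, progress
toward any developmental milestone) conventionally use ``alpha`` fixed at
3.5; gas-exchange processes fit ``alpha`` freely within bounds.

Note that ``T0`` is *not* the argmax of the curve: with the development
parameterization (dHa = 69.1 kJ mol⁻¹, T0 = 29.2 °C) the true optimum sits
near 26.5 °C.  :func:`find_optimum` always locates the argmax numerically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "ALPHA_DEVELOPMENT",
    "ResponseParams",
    "response_rate",
    "normalized_response",
    "find_optimum",
    "fit_response",
    "FitResult",
    "OptimumResult",
]

#: Universal gas constant, J mol⁻¹ K⁻¹.
GAS_CONSTANT = 8.314

#: Offset between °C and K.
CELSIUS_OFFSET = 273.15

#: Conventional fixed sharpness for development-class processes.
ALPHA_DEVELOPMENT = 3.5

# Fitting bounds (dHa in J/mol, T0 in K, alpha dimensionless).
_DHA_BOUNDS = (1.0e3, 400.0e3)
_T0_BOUNDS = (273.15, 333.15)
_ALPHA_BOUNDS = (0.5, 20.0)


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of one temperature-response curve.

    Attributes
    ----------
    A : float
        Trait scaling coefficient (trait units per K-weighted Arrhenius
        term); strictly positive.
    dHa : float
        Enthalpy of activation, J mol⁻¹; strictly positive.
    alpha : float
        High-temperature sharpness, dimensionless; strictly positive.
    T0 : float
        Temperature parameter of the high-temperature decline, Kelvin.
    """

    A: float
    dHa: float
    alpha: float
    T0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and self.A > 0):
            raise ValueError(f"A must be finite and > 0, got {self.A}")
        if not (np.isfinite(self.dHa) and self.dHa > 0):
            raise ValueError(f"dHa must be finite and > 0, got {self.dHa}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")
        if not np.isfinite(self.T0):
            raise ValueError(f"T0 must be finite, got {self.T0}")

    def scaled_to(self, value: float, temperature: float = 20.0) -> "ResponseParams":
        """Return a copy with ``A`` rescaled so F(temperature) == value."""
        if value <= 0:
            raise ValueError("target value must be > 0")
        current = response_rate(self, temperature)
        return replace(self, A=self.A * value / current)

    def to_dict(self) -> dict:
        return {"A": self.A, "dHa_J_per_mol": self.dHa, "alpha": self.alpha,
                "T0_K": self.T0}

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseParams":
        return cls(A=float(d["A"]), dHa=float(d["dHa_J_per_mol"]),
                   alpha=float(d["alpha"]), T0=float(d["T0_K"]))


def _check_temperature(temperature) -> np.ndarray:
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    if np.any(t <= -CELSIUS_OFFSET):
        raise ValueError("temperature must be above absolute zero (> -273.15 °C)")
    return t


def _log_rate(params: ResponseParams, temperature) -> np.ndarray:
    """log F(T), evaluated in log-space so no overflow occurs for any
    temperature in (-50, 80) °C."""
    T = _check_temperature(temperature) + CELSIUS_OFFSET
    arrhenius = -params.dHa / (GAS_CONSTANT * T)
    # denominator exponent: [exp(-dHa/RT)]^(alpha (1 - T/T0))
    g = arrhenius * params.alpha * (1.0 - T / params.T0)
    return math.log(params.A) + np.log(T) + arrhenius - np.logaddexp(0.0, g)


def response_rate(params: ResponseParams, temperature):
    """Evaluate F(T) at a temperature (or array of temperatures) in °C.

    Strictly positive for all valid inputs.  At ``T == T0`` the denominator
    is exactly 2.
    """
    out = np.exp(_log_rate(params, temperature))
    return float(out) if np.ndim(temperature) == 0 else out


def normalized_response(params: ResponseParams, temperature, reference: float = 20.0):
    """F(T) / F(T_ref): the response normalized to its value at a reference
    temperature (default 20 °C).  Independent of the scaling ``A``."""
    out = np.exp(_log_rate(params, temperature) - _log_rate(params, reference))
    return float(out) if np.ndim(temperature) == 0 else out


@dataclass(frozen=True)
class OptimumResult:
    """Optimum temperature of a response curve, °C, with a quality flag."""

    temperature: float
    rate: float
    boundary_warning: bool = False

    def __float__(self) -> float:
        return self.temperature


def find_optimum(params: ResponseParams, *, tol: float = 0.01) -> OptimumResult:
    """Locate the temperature (°C) maximizing F over [0 °C, T0 − 273.15 + 15].

    Uses bounded scalar minimization of −log F to a tolerance of ``tol`` °C
    (default 0.01).  If the maximum is attained at (or within tolerance of)
    an interval boundary, the result carries ``boundary_warning=True``.
    """
    lo, hi = 0.0, params.T0 - CELSIUS_OFFSET + 15.0
    res = optimize.minimize_scalar(
        lambda t: -_log_rate(params, t), bounds=(lo, hi), method="bounded",
        options={"xatol": tol / 4.0},
    )
    t_opt = float(res.x)
    warn = t_opt - lo < 10 * tol or hi - t_opt < 10 * tol
    return OptimumResult(temperature=t_opt, rate=response_rate(params, t_opt),
                         boundary_warning=warn)


@dataclass(frozen=True)
class FitResult:
    """A fitted response curve plus its goodness of fit."""

    params: ResponseParams
    r_squared: float
    converged: bool = True

    def to_json(self) -> str:
        d = self.params.to_dict()
        d["r_squared"] = self.r_squared
        return json.dumps(d, indent=2)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_response(
    observations: Sequence[tuple[float, float]],
    *,
    fix_alpha: float | None = None,
    seed: int = 0,
    n_starts: int = 10,
) -> FitResult:
    """Fit the response curve to (temperature °C, rate) observations.

    Nonlinear least squares on the untransformed rate scale, with ``A``
    parameterized on a log scale (it balances an Arrhenius factor of order
    1e-13, so spans many orders of magnitude).  ``fix_alpha`` pins the
    sharpness (use :data:`ALPHA_DEVELOPMENT` for development-class
    processes); otherwise alpha is free within [0.5, 20].

    Multi-start (default 10 seeded starts) makes the outcome deterministic
    for a given ``seed`` and robust to the non-convex objective.  Requires
    rates > 0 and at least 4 distinct temperatures (5 when alpha is free).

    Returns
    -------
    FitResult
        Fitted :class:`ResponseParams` and R² on the rate scale.

    Raises
    ------
    ValueError
        If the data under-determine the parameters or rates are not
        positive.
    RuntimeError
        If no start converges; the best candidate is attached to the
        exception as ``exc.best``.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be (temperature, rate) pairs")
    t_obs, y_obs = obs[:, 0], obs[:, 1]
    _check_temperature(t_obs)
    if np.any(y_obs <= 0):
        raise ValueError("rates must be strictly positive")
    n_params = 3 if fix_alpha is not None else 4
    n_temps = len(np.unique(t_obs))
    min_temps = 4 if fix_alpha is not None else 5
    if n_temps < min_temps or n_temps < n_params:
        raise ValueError(
            f"need at least {min_temps} distinct temperatures for "
            f"{n_params} parameters, got {n_temps}"
        )

    free_alpha = fix_alpha is None

    def unpack(theta):
        log_a, dha, t0 = theta[0], theta[1], theta[2]
        alpha = theta[3] if free_alpha else fix_alpha
        return ResponseParams(A=math.exp(log_a), dHa=dha, alpha=alpha, T0=t0)

    def residuals(theta):
        p = unpack(theta)
        return response_rate(p, t_obs) - y_obs

    def log_a_for(dha, alpha, t0):
        # choose A so the unit curve matches the mean observed rate
        probe = ResponseParams(A=1.0, dHa=dha, alpha=alpha, T0=t0)
        mean_log = float(np.mean(_log_rate(probe, t_obs)))
        return math.log(max(np.mean(y_obs), 1e-300)) - mean_log

    rng = np.random.default_rng(seed)
    lower = [-700.0, _DHA_BOUNDS[0], _T0_BOUNDS[0]]
    upper = [700.0, _DHA_BOUNDS[1], _T0_BOUNDS[1]]
    if free_alpha:
        lower.append(_ALPHA_BOUNDS[0])
        upper.append(_ALPHA_BOUNDS[1])

    # deterministic first start + seeded random restarts
    starts = []
    dha0, t00 = 60.0e3, max(t_obs) + CELSIUS_OFFSET + 3.0
    alpha0 = 3.5
    t00 = min(max(t00, _T0_BOUNDS[0] + 1), _T0_BOUNDS[1] - 1)
    starts.append((dha0, alpha0, t00))
    for _ in range(n_starts - 1):
        dha = math.exp(rng.uniform(math.log(5e3), math.log(3e5)))
        alpha = rng.uniform(1.0, 8.0) if free_alpha else fix_alpha
        t0 = rng.uniform(max(t_obs) + CELSIUS_OFFSET - 2.0,
                         min(_T0_BOUNDS[1] - 1, max(t_obs) + CELSIUS_OFFSET + 25.0))
        starts.append((dha, alpha, t0))

    best = None
    best_cost = np.inf
    for dha, alpha, t0 in starts:
        theta0 = [log_a_for(dha, alpha, t0), dha, t0]
        if free_alpha:
            theta0.append(alpha)
        try:
            sol = optimize.least_squares(residuals, theta0,
                                         bounds=(lower, upper), method="trf")
        except Exception:  # numerical failure of one start is not fatal
            continue
        if sol.cost < best_cost:
            best_cost, best = sol.cost, sol
    if best is None:
        exc = RuntimeError("temperature-response fit failed to converge")
        exc.best = None
        raise exc

    params = unpack(best.x)
    r2 = _r_squared(y_obs, response_rate(params, t_obs))
    return FitResult(params=params, r_squared=r2, converged=bool(best.success))
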