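"""Constrained 3-parameter logistic model of grain filling.

Single-grain dry weight after anthesis follows a logistic reparameterized
so the weight at anthesis, ``W_0`` (mg), is itself a parameter:

.. math::

    W(t) = W_0 \\frac{1 + e^{\\lambda t_0}}{1 + e^{-\\lambda (t - t_0)}}

``t_0`` is the inflection time (half of final weight, maximal growth rate)
and ``lambda`` the slope factor.  Time may be clock days or developmental
days (d_20°C); parameters carry their basis, and rescaling time by a
factor f maps (t_0, λ) → (t_0·f, λ/f) leaving predicted weights unchanged.

Derived quantities:

* grain growth rate  GGR(t) = dW/dt, maximal at t_0;
* GGR_max = λ W_0 (1 + e^{λ t_0}) / 4, interchangeable with λ once W_0
  and t_0 are fixed (``lambda_from_ggrmax`` inverts it);
* filling duration  t_f = t_0 + ln(19)/λ, the time to 95 % of final weight.

Fitting conventions: W_0 is common to all treatments (plants were split to
thermal treatments at anthesis), and in developmental time a single
``t_0.20°C`` can be shared across treatments, leaving λ as each
treatment's only free parameter.  Spikes with fewer than 30 seeds are
excluded before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GrainGrowthParams",
    "GrainFitResult",
    "SharedT0Fit",
    "weight_at",
    "ggr",
    "ggr_max",
    "lambda_from_ggrmax",
    "filling_duration",
    "fit_logistic",
    "shared_t0_fit",
    "filter_spikes",
    "W0_DEFAULT",
    "T0_20_DEFAULT",
    "MIN_SEED_COUNT",
]

#: Conventional fixed grain weight at anthesis, mg.
W0_DEFAULT = 1.65
#: Conventional common inflection time in developmental units, d_20°C.
T0_20_DEFAULT = 20.2
#: Spikes with fewer seeds than this are excluded from fitting.
MIN_SEED_COUNT = 30


@dataclass(frozen=True)
class GrainGrowthParams:
    """Logistic grain-filling parameters, tagged with their time basis."""

    w0: float
    t0: float
    lam: float
    time_basis: str = "clock"  # "clock" or "developmental"

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError(f"w0 must be > 0, got {self.w0}")
        if self.t0 <= 0:
            raise ValueError(f"t0 must be > 0, got {self.t0}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.time_basis not in ("clock", "developmental"):
            raise ValueError(f"unknown time_basis {self.time_basis!r}")

    @property
    def final_weight(self) -> float:
        """Asymptotic grain weight, mg."""
        return self.w0 * (1.0 + np.exp(self.lam * self.t0))

    def rescaled(self, factor: float) -> "GrainGrowthParams":
        """Change time basis by a factor f: (t0, λ) → (t0·f, λ/f).

        Predicted weights at corresponding times are identical."""
        basis = "developmental" if self.time_basis == "clock" else "clock"
        return replace(self, t0=self.t0 * factor, lam=self.lam / factor,
                       time_basis=basis)


def weight_at(params: GrainGrowthParams, t):
    """Grain weight (mg) at time(s) t >= 0; W(0) == w0 exactly."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam, t0 = params.lam, params.t0
    # numerator written with logaddexp-free care: exp(lam*t0) is modest for
    # biological ranges (lam*t0 ~ 3), no overflow concern
    out = params.w0 * (1.0 + np.exp(lam * t0)) / (1.0 + np.exp(-lam * (t - t0)))
    return float(out) if out.ndim == 0 else out


def ggr(params: GrainGrowthParams, t):
    """Grain growth rate dW/dt (mg per d, or per d_20°C): the analytic
    logistic derivative, positive and unimodal with its maximum at t0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam, t0 = params.lam, params.t0
    e = np.exp(-lam * (t - t0))
    out = lam * params.w0 * (1.0 + np.exp(lam * t0)) * e / (1.0 + e) ** 2
    return float(out) if out.ndim == 0 else out


def ggr_max(params: GrainGrowthParams) -> float:
    """Maximum grain growth rate, attained at t0: λ W_0 (1 + e^{λ t_0}) / 4."""
    return params.lam * params.w0 * (1.0 + np.exp(params.lam * params.t0)) / 4.0


def lambda_from_ggrmax(ggrmax: float, w0: float = W0_DEFAULT,
                       t0: float = T0_20_DEFAULT) -> float:
    """Invert GGR_max for λ at fixed (w0, t0) by bracketed root solving.

    Solves λ (1 + e^{λ t0}) = 4·GGR_max / w0 for λ in (0, 2];
    round-trips with :func:`ggr_max` to better than 1e-8 relative.
    """
    if ggrmax <= 0:
        raise ValueError(f"ggrmax must be > 0, got {ggrmax}")
    target = 4.0 * ggrmax / w0

    def f(lam):
        return lam * (1.0 + np.exp(lam * t0)) - target

    lo, hi = 1e-12, 2.0
    if f(hi) < 0:
        raise ValueError(
            f"GGR_max {ggrmax} out of range: no λ in (0, 2] at w0={w0}, t0={t0}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def filling_duration(params: GrainGrowthParams) -> float:
    """Grain filling duration t_f = t_0 + ln(19)/λ: the time from anthesis
    to 95 % of final weight (exactly, by the logistic closed form)."""
    return params.t0 + np.log(19.0) / params.lam


@dataclass(frozen=True)
class GrainFitResult:
    params: GrainGrowthParams
    r_squared: float
    t0_se: float | None = None
    lam_se: float | None = None
    all_pre_inflection: bool = False


def fit_logistic(
    series: Sequence[tuple[float, float]] | np.ndarray,
    *,
    fixed_w0: float = W0_DEFAULT,
    fixed_t0: float | None = None,
    time_basis: str = "clock",
) -> GrainFitResult:
    """Nonlinear least-squares logistic fit with W_0 fixed.

    Free parameters are (t0, λ), or λ alone when ``fixed_t0`` is given.
    Deterministic (single analytic start).  Warns via the result's
    ``all_pre_inflection`` flag when no observation exceeds half the fitted
    final weight.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (t, weight) pairs")
    t, y = arr[:, 0], arr[:, 1]
    if np.any(y <= 0):
        raise ValueError("grain weights must be positive")
    n_free = 1 if fixed_t0 is not None else 2
    if len(np.unique(t)) < n_free + 2:
        raise ValueError("too few distinct time points for the free parameters")

    w_max = float(y.max())
    lam0 = 0.15
    t00 = fixed_t0 if fixed_t0 is not None else float(np.median(t))

    def predict(t0, lam):
        p = GrainGrowthParams(w0=fixed_w0, t0=t0, lam=lam, time_basis=time_basis)
        return weight_at(p, t)

    if fixed_t0 is None:
        def residuals(theta):
            return predict(theta[0], theta[1]) - y
        theta0 = [max(t00, 1e-3), lam0]
        bounds = ([1e-3, 1e-4], [max(t.max(), t00) * 2 + 10, 2.0])
    else:
        def residuals(theta):
            return predict(fixed_t0, theta[0]) - y
        theta0 = [lam0]
        bounds = ([1e-4], [2.0])

    sol = optimize.least_squares(residuals, theta0, bounds=bounds, method="trf",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        exc = RuntimeError("logistic grain-growth fit failed to converge")
        exc.best = sol
        raise exc
    if fixed_t0 is None:
        t0_hat, lam_hat = float(sol.x[0]), float(sol.x[1])
    else:
        t0_hat, lam_hat = float(fixed_t0), float(sol.x[0])
    params = GrainGrowthParams(w0=fixed_w0, t0=t0_hat, lam=lam_hat,
                               time_basis=time_basis)
    pred = weight_at(params, t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # asymptotic standard errors from the Jacobian (for shared-t0 weighting)
    t0_se = lam_se = None
    dof = len(y) - len(sol.x)
    if dof > 0:
        s2 = 2.0 * sol.cost / dof
        try:
            cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
            ses = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            if fixed_t0 is None:
                t0_se, lam_se = float(ses[0]), float(ses[1])
            else:
                lam_se = float(ses[0])
        except np.linalg.LinAlgError:
            pass

    pre_inflection = w_max < 0.5 * params.final_weight
    return GrainFitResult(params=params, r_squared=r2, t0_se=t0_se,
                          lam_se=lam_se, all_pre_inflection=pre_inflection)


@dataclass(frozen=True)
class SharedT0Fit:
    """Three-stage shared-inflection fit across treatments.

    stage1: per-treatment free (t0, λ) fits;
    t0_common: inverse-variance-weighted mean of stage-1 t0 estimates;
    stage3: per-treatment λ refits with t0 fixed at ``t0_common``.
    """

    stage1: dict
    t0_common: float
    stage3: dict
    excluded: tuple = ()


def shared_t0_fit(
    series_by_treatment: Mapping[str, Sequence[tuple[float, float]]],
    *,
    fixed_w0: float = W0_DEFAULT,
    time_basis: str = "developmental",
) -> SharedT0Fit:
    """Fit a common inflection time across >= 2 treatments.

    Stage 1 fits (t0, λ) freely per treatment; stage 2 takes the
    inverse-variance-weighted mean of the t0 estimates (equal weights where
    standard errors are unavailable); stage 3 refits λ per treatment with
    t0 pinned to the common value.  Treatments whose stage-1 fit fails are
    excluded with a warning.
    """
    if len(series_by_treatment) < 2:
        raise ValueError("need at least 2 treatments; use fit_logistic for one")

    stage1, excluded = {}, []
    for name, series in series_by_treatment.items():
        try:
            stage1[name] = fit_logistic(series, fixed_w0=fixed_w0,
                                        time_basis=time_basis)
        except (RuntimeError, ValueError) as e:
            warnings.warn(f"treatment {name!r} excluded from shared-t0 fit: {e}",
                          RuntimeWarning)
            excluded.append(name)
    if not stage1:
        raise RuntimeError("all treatments failed the stage-1 fit")

    t0s = np.array([f.params.t0 for f in stage1.values()])
    ses = np.array([f.t0_se if f.t0_se and f.t0_se > 0 else np.nan
                    for f in stage1.values()])
    if np.any(np.isnan(ses)):
        weights = np.ones_like(t0s)
    else:
        weights = 1.0 / ses**2
    t0_common = float(np.sum(weights * t0s) / np.sum(weights))

    stage3 = {
        name: fit_logistic(series_by_treatment[name], fixed_w0=fixed_w0,
                           fixed_t0=t0_common, time_basis=time_basis)
        for name in stage1
    }
    return SharedT0Fit(stage1=stage1, t0_common=t0_common, stage3=stage3,
                       excluded=tuple(excluded))


def filter_spikes(df: pd.DataFrame, *, seed_count_col: str = "seed_count",
                  min_seeds: int = MIN_SEED_COUNT) -> pd.DataFrame:
    """Exclude spikes with fewer than ``min_seeds`` seeds before fitting."""
    if seed_count_col not in df.columns:
        return df
    return df[df[seed_count_col] >= min_seeds].copy()
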