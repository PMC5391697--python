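"""Bilinear (plateau-then-decline) model of leaf chlorophyll loss.

SPAD chlorophyll readings after anthesis stay on a plateau ``SPAD_0`` until
senescence begins at ``t_s``, then fall linearly with slope ``a_s`` (< 0):

    SPAD(t) = SPAD_0                         for t <= t_s
    SPAD(t) = SPAD_0 + a_s (t - t_s)         for t >  t_s

The time axis may be clock days or developmental days (d_20°C); the fit is
agnostic, and re-expressing time by a factor f maps (t_s, a_s) to
(t_s × f, a_s / f).

The plateau is conventionally fixed across thermal treatments to the mean
SPAD at anthesis (all plants shared the pre-anthesis regime); the fitter
accepts it fixed or free.  Breakpoint estimation profiles t_s over a 0.1 d
grid with the conditional linear fit in closed form, then polishes the best
grid point by bounded local optimization — the objective is continuous but
non-smooth in t_s, so grid+polish is deterministic and robust.

Confidence intervals are case-resampling bootstrap percentile intervals;
the resampling unit is the plant (a whole repeatedly-measured time course)
when plant identities are available, single observations otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SenescenceParams",
    "SenescenceFit",
    "DegenerateFitError",
    "bilinear_value",
    "fit_bilinear",
    "bootstrap_ci",
    "SPAD0_DEFAULT",
]

#: Conventional fixed plateau: mean SPAD at anthesis across treatments.
SPAD0_DEFAULT = 57.3


class DegenerateFitError(RuntimeError):
    """Raised when a SPAD series shows no detectable post-onset decline."""


@dataclass(frozen=True)
class SenescenceParams:
    """Bilinear senescence parameters: plateau, onset time and decline slope."""

    spad0: float
    t_s: float
    a_s: float

    def __post_init__(self) -> None:
        if self.spad0 <= 0:
            raise ValueError(f"spad0 must be > 0, got {self.spad0}")
        if self.t_s < 0:
            raise ValueError(f"t_s must be >= 0, got {self.t_s}")


@dataclass(frozen=True)
class SenescenceFit:
    params: SenescenceParams
    r_squared: float


def bilinear_value(params: SenescenceParams, t):
    """SPAD predicted at time(s) ``t`` (>= 0); floored at 0 — chlorophyll
    content cannot be negative."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.where(t <= params.t_s, params.spad0,
                   params.spad0 + params.a_s * (t - params.t_s))
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def _conditional_sse(t: np.ndarray, y: np.ndarray, ts: float,
                     fixed_spad0: float | None):
    """Best (spad0, a_s) and SSE for a candidate breakpoint (no floor)."""
    post = np.maximum(t - ts, 0.0)
    if fixed_spad0 is None:
        X = np.column_stack([np.ones_like(t), post])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        spad0, a_s = float(coef[0]), float(coef[1])
    else:
        spad0 = fixed_spad0
        denom = float(post @ post)
        a_s = float(post @ (y - spad0)) / denom if denom > 0 else 0.0
    resid = y - (spad0 + a_s * post)
    return spad0, a_s, float(resid @ resid)


def fit_bilinear(
    series: Sequence[tuple[float, float]] | np.ndarray,
    *,
    fixed_spad0: float | None = SPAD0_DEFAULT,
    grid_step: float = 0.1,
) -> SenescenceFit:
    """Least-squares bilinear fit to a (time, SPAD) series.

    ``fixed_spad0`` pins the plateau (the pipeline default fixes it to the
    cross-treatment anthesis mean, 57.3); pass ``None`` to fit it freely.
    ``t_s`` is constrained to the observed time range.

    Raises
    ------
    DegenerateFitError
        If no decline is detectable (all observations effectively
        pre-onset, or the best-fit slope is non-negative).
    ValueError
        If fewer than 4 distinct time points are supplied.
    """
    arr = np.asarray(list(series), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (t, spad) pairs")
    t, y = arr[:, 0], arr[:, 1]
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct time points")

    t_min, t_max = float(t.min()), float(t.max())
    grid = np.arange(t_min, t_max + grid_step / 2, grid_step)

    def sse_of(ts):
        return _conditional_sse(t, y, float(ts), fixed_spad0)[2]

    sses = np.array([sse_of(ts) for ts in grid])
    i_best = int(np.argmin(sses))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-6})
        ts_best = float(res.x) if res.fun <= sses[i_best] else float(grid[i_best])
    else:
        ts_best = float(grid[i_best])

    spad0, a_s, sse = _conditional_sse(t, y, ts_best, fixed_spad0)
    n_post = int(np.sum(t > ts_best))
    if n_post < 2 or a_s >= 0:
        raise DegenerateFitError(
            "no post-onset decline detectable: all observations lie on the "
            "plateau or the fitted slope is non-negative"
        )
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    return SenescenceFit(
        params=SenescenceParams(spad0=spad0, t_s=max(ts_best, 0.0), a_s=a_s),
        r_squared=r2,
    )


def bootstrap_ci(
    data: pd.DataFrame,
    *,
    fixed_spad0: float | None = SPAD0_DEFAULT,
    reps: int = 1000,
    seed: int = 0,
    unit: str = "observation",
    time_col: str = "days_after_anthesis",
    spad_col: str = "spad",
    plant_col: str = "plant_id",
    level: float = 0.95,
) -> dict:
    """Bootstrap percentile confidence intervals for the bilinear parameters.

    Case resampling with replacement; ``unit`` selects what is resampled.
    The default, ``"observation"``, resamples single readings, appropriate
    when measurement noise dominates.  ``unit="plant"`` resamples whole
    repeatedly-measured time courses (requires a ``plant_id`` column) and
    is the right choice when plants differ systematically — but with very
    few plants (e.g. four) it admits only a handful of distinct resamples
    and its percentile intervals undercover noticeably.

    Replicates whose refit is degenerate are dropped and counted; a warning
    is emitted if more than 20 % drop.

    Returns a dict with keys ``spad0``, ``t_s``, ``a_s`` mapping to
    ``(low, high)`` tuples, plus ``n_dropped`` and ``reps``.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if unit not in ("observation", "plant"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    rng = np.random.default_rng(seed)
    has_plants = unit == "plant"
    if has_plants and plant_col not in data.columns:
        raise ValueError("unit='plant' requires a plant_id column")
    if has_plants:
        groups = [g[[time_col, spad_col]].to_numpy(float)
                  for _, g in data.groupby(plant_col)]
    else:
        rows = data[[time_col, spad_col]].to_numpy(float)

    samples = {"spad0": [], "t_s": [], "a_s": []}
    n_dropped = 0
    for _ in range(reps):
        if has_plants:
            idx = rng.integers(0, len(groups), size=len(groups))
            arr = np.vstack([groups[i] for i in idx])
        else:
            idx = rng.integers(0, len(rows), size=len(rows))
            arr = rows[idx]
        try:
            fit = fit_bilinear(arr, fixed_spad0=fixed_spad0)
        except (DegenerateFitError, ValueError):
            n_dropped += 1
            continue
        samples["spad0"].append(fit.params.spad0)
        samples["t_s"].append(fit.params.t_s)
        samples["a_s"].append(fit.params.a_s)

    if n_dropped > 0.2 * reps:
        warnings.warn(
            f"{n_dropped}/{reps} bootstrap replicates dropped as degenerate",
            RuntimeWarning,
        )
    tail = (1.0 - level) / 2.0
    out = {
        key: (float(np.quantile(vals, tail)), float(np.quantile(vals, 1 - tail)))
        for key, vals in samples.items()
    }
    out["n_dropped"] = n_dropped
    out["reps"] = reps
    return out
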