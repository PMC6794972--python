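"""Least-squares estimation of the occlusion rate per paste and saliva condition.

Each paste × saliva-condition group contributes one daily mean series (days
1..7 in the bundled study).  The occlusion rate ``r`` — and, depending on
policy, the latent initial occlusion ``x0`` — is estimated by minimizing the
(optionally inverse-variance weighted) sum of squared deviations between the
observed daily means and the closed-form logistic trajectory, with the
carrying capacity ``K`` held fixed at 100 %.

Because the study never states how the initial value was handled, three
``x0_policy`` modes are provided and a sensitivity sweep over them is part of
the standard analysis:

``"fitted"`` (default)
    ``x0`` estimated jointly with ``r``, bounded inside ``(0, K)``.
``"anchored"``
    ``x0`` fixed by back-projecting the first observed mean: the trajectory
    is constrained to pass exactly through the first (day, mean) point, and
    only ``r`` is free.
a number
    ``x0`` fixed at that value.

Optimization is a deterministic bounded multi-start: initial SSE is evaluated
on a fixed 5x5 grid of ``(r, x0)`` starting points, the best-ranked starts
are refined with L-BFGS-B using the analytic gradient, and the overall best
refined point is returned.  The returned SSE never exceeds the SSE at any
grid start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model import LogisticParams, trajectory_on_grid

__all__ = [
    "OcclusionSeries",
    "FitResult",
    "InsufficientDataError",
    "NonConvergenceError",
    "sse_objective",
    "fit_logistic",
    "fit_all_groups",
    "goodness_of_fit",
    "fit_report_frame",
]

R_BOUNDS = (1e-6, 10.0)
#: fixed deterministic multi-start grid (occlusion rate axis)
R_STARTS = (0.02, 0.1, 0.5, 2.0, 8.0)
#: fixed deterministic multi-start grid (x0 axis, as fractions of K)
X0_START_FRACS = (0.02, 0.1, 0.3, 0.6, 0.9)


class InsufficientDataError(ValueError):
    """Raised when a series has too few points to identify the model."""


class NonConvergenceError(RuntimeError):
    """Raised when no multi-start run converges; carries the best attempt."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class OcclusionSeries:
    """Summary time series for one paste under one saliva condition.

    ``days`` are observation day indices (strictly increasing), ``means`` and
    ``sds`` the per-day mean and standard deviation of the % occluded area
    over the ``n`` specimens of the group.
    """

    paste: str
    condition: str
    days: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.days.shape == self.means.shape == self.sds.shape):
            raise ValueError("days, means and sds must have equal lengths")
        if self.days.ndim != 1 or self.days.size == 0:
            raise ValueError("series must hold at least one observation day")
        if not np.all(np.isfinite(self.days)) or not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be finite and strictly increasing")
        if not np.all((self.means >= 0) & (self.means <= 100)):
            raise ValueError("means must lie in [0, 100] percent")
        if not np.all(self.sds >= 0):
            raise ValueError("sds must be non-negative")
        self.n = int(self.n)
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def __len__(self) -> int:
        return self.days.size


@dataclass
class FitResult:
    """Outcome of one least-squares fit (one paste × condition cell)."""

    params: LogisticParams | None
    sse: float
    rmse: float
    r_squared: float
    converged: bool
    n_points: int
    x0_policy: str
    multistart_r_spread: float | None = None
    error: str | None = None


def _weight_vector(series: OcclusionSeries, weights: str) -> np.ndarray:
    if weights == "unweighted":
        return np.ones_like(series.means)
    if weights == "inverse_variance":
        if np.any(series.sds == 0):
            raise ValueError(
                "inverse_variance weighting is undefined when any sd is zero; "
                "use weights='unweighted' for this series"
            )
        return series.n / series.sds**2
    raise ValueError(f"unknown weights policy {weights!r}")


def sse_objective(
    series: OcclusionSeries, params: LogisticParams, weights: str = "unweighted"
) -> float:
    """Weighted sum of squared residuals of the closed-form trajectory.

    Zero exactly when the trajectory interpolates every observed mean.
    ``inverse_variance`` weights each day by ``n / sd^2`` (the reciprocal
    variance of the daily mean).
    """
    w = _weight_vector(series, weights)
    pred = trajectory_on_grid(params, series.days)
    return float(np.sum(w * (series.means - pred) ** 2))


def _predict_and_grad(theta, t, K, policy, anchor):
    """Trajectory and its gradient w.r.t. the free parameters.

    ``policy`` is "fitted" (theta = [r, x0]), "anchored" (theta = [r], the
    curve passes through ``anchor = (d1, m1)``) or "fixed" (theta = [r], x0
    = ``anchor``).  Returns (X, J) with J of shape (len(t), len(theta)).
    """
    if policy == "fitted":
        r, x0 = theta
        X = K * expit(logit(x0 / K) + r * t)
        g = X * (1.0 - X / K)  # = dX d(logit-argument)
        J = np.column_stack((t * g, g * K / (x0 * (K - x0))))
    elif policy == "anchored":
        (r,) = theta
        d1, m1 = anchor
        X = K * expit(logit(m1 / K) + r * (t - d1))
        g = X * (1.0 - X / K)
        J = ((t - d1) * g)[:, None]
    else:  # fixed x0
        (r,) = theta
        x0 = anchor
        X = K * expit(logit(x0 / K) + r * t)
        g = X * (1.0 - X / K)
        J = (t * g)[:, None]
    return X, J


def _x0_from_theta(theta, K, policy, anchor) -> float:
    if policy == "fitted":
        return float(theta[1])
    if policy == "anchored":
        d1, m1 = anchor
        # back-project the anchored curve to t = 0
        return float(K * expit(logit(m1 / K) - theta[0] * d1))
    return float(anchor)


def fit_logistic(
    series: OcclusionSeries,
    K: float = 100.0,
    x0_policy: "str | float" = "fitted",
    weights: str = "unweighted",
    refine_top: int = 5,
    refine_all: bool = False,
) -> FitResult:
    """Bounded least-squares fit of the logistic trajectory to daily means.

    Parameters
    ----------
    series
        Daily summary series for one paste × condition group.
    K
        Carrying capacity, held fixed (not estimated); 100 % by default.
    x0_policy
        ``"fitted"``, ``"anchored"`` or a numeric fixed value (see module
        docstring).
    weights
        ``"unweighted"`` (default; curves are fitted to the mean series) or
        ``"inverse_variance"``.
    refine_top
        Number of best-ranked grid starts refined with L-BFGS-B.
    refine_all
        Refine every grid start; additionally reports the spread of the
        fitted rate across converged starts (multimodality flag).

    Raises
    ------
    InsufficientDataError
        Fewer than 3 observation days.
    NonConvergenceError
        No refined start converged; the exception carries the best attempt.
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"need at least 3 data points to fit, got {len(series)}"
        )
    if K <= np.max(series.means):
        warnings.warn(
            f"K={K} does not exceed the largest observed mean "
            f"({np.max(series.means)}); the model cannot reach that value",
            stacklevel=2,
        )

    t = series.days
    y = series.means
    w = _weight_vector(series, weights)
    x0_bounds = (1e-6, K - 1e-6)

    if isinstance(x0_policy, str) and x0_policy == "fitted":
        policy, anchor, policy_label = "fitted", None, "fitted"
        starts = [(r0, f * K) for r0 in R_STARTS for f in X0_START_FRACS]
        bounds = [R_BOUNDS, x0_bounds]
    elif isinstance(x0_policy, str) and x0_policy == "anchored":
        d1, m1 = float(t[0]), float(y[0])
        if not 0.0 < m1 < K:
            raise ValueError(
                "anchored policy needs the first mean strictly inside (0, K)"
            )
        policy, anchor, policy_label = "anchored", (d1, m1), "anchored_day1"
        starts = [(r0,) for r0 in R_STARTS]
        bounds = [R_BOUNDS]
    else:
        v = float(x0_policy)
        if not 0.0 < v < K:
            raise ValueError(f"fixed x0 must lie strictly inside (0, K), got {v}")
        policy, anchor, policy_label = "fixed", v, f"fixed_at_{v:g}"
        starts = [(r0,) for r0 in R_STARTS]
        bounds = [R_BOUNDS]

    def objective(theta):
        X, J = _predict_and_grad(np.asarray(theta, float), t, K, policy, anchor)
        res = y - X
        f = np.sum(w * res**2)
        grad = -2.0 * (w * res) @ J
        return f, grad

    init = [(objective(s)[0], s) for s in starts]
    init.sort(key=lambda p: p[0])
    n_refine = len(init) if refine_all else min(refine_top, len(init))

    best = None
    converged_rs: list[float] = []
    any_success = False
    for f0, s in init[:n_refine]:
        res = minimize(
            objective,
            np.asarray(s, float),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        if res.success:
            any_success = True
            converged_rs.append(float(res.x[0]))
        if best is None or res.fun < best.fun:
            best = res

    sse = float(best.fun)
    # dominance safeguard: never worse than the best raw start
    if sse > init[0][0]:
        sse = init[0][0]
        best_theta = np.asarray(init[0][1], float)
    else:
        best_theta = best.x

    r_hat = float(best_theta[0])
    x0_hat = _x0_from_theta(best_theta, K, policy, anchor)
    params = LogisticParams(r=r_hat, K=K, x0=x0_hat)
    rmse, r2 = goodness_of_fit(series, params)
    spread = (
        max(converged_rs) - min(converged_rs)
        if refine_all and converged_rs
        else None
    )
    result = FitResult(
        params=params,
        sse=sse,
        rmse=rmse,
        r_squared=r2,
        converged=any_success,
        n_points=len(series),
        x0_policy=policy_label,
        multistart_r_spread=spread,
    )
    if not any_success:
        raise NonConvergenceError(
            f"no multi-start run converged for {series.paste} / {series.condition}",
            best=result,
        )
    return result


def fit_all_groups(
    table: Sequence[OcclusionSeries],
    K: float = 100.0,
    x0_policy: "str | float" = "fitted",
    weights: str = "unweighted",
) -> list[FitResult]:
    """Fit every series of a study table; failures are flagged, not fatal."""
    if len(table) == 0:
        raise ValueError("table must contain at least one series")
    results: list[FitResult] = []
    for series in table:
        try:
            results.append(fit_logistic(series, K=K, x0_policy=x0_policy, weights=weights))
        except NonConvergenceError as exc:
            best = exc.best or FitResult(
                params=None, sse=np.nan, rmse=np.nan, r_squared=np.nan,
                converged=False, n_points=len(series), x0_policy=str(x0_policy),
            )
            best.error = str(exc)
            best.converged = False
            results.append(best)
        except (ValueError, InsufficientDataError) as exc:
            results.append(
                FitResult(
                    params=None, sse=np.nan, rmse=np.nan, r_squared=np.nan,
                    converged=False, n_points=len(series),
                    x0_policy=str(x0_policy), error=str(exc),
                )
            )
    return results


def goodness_of_fit(
    series: OcclusionSeries, params: LogisticParams
) -> tuple[float, float]:
    """Root-mean-square error and R² of a trajectory against a series.

    R² is computed about the series mean; for a constant series the total
    sum of squares vanishes and R² is reported as ``nan`` (undefined).
    """
    sse = sse_objective(series, params, weights="unweighted")
    rmse = float(np.sqrt(sse / len(series)))
    tss = float(np.sum((series.means - series.means.mean()) ** 2))
    r2 = float("nan") if tss == 0.0 else 1.0 - sse / tss
    return rmse, r2


def fit_report_frame(
    table: Sequence[OcclusionSeries], results: Sequence[FitResult]
) -> pd.DataFrame:
    """Tabular fit report: one row per paste × condition cell."""
    rows = []
    for s, res in zip(table, results):
        rows.append(
            {
                "paste": s.paste,
                "condition": s.condition,
                "r": res.params.r if res.params else np.nan,
                "x0": res.params.x0 if res.params else np.nan,
                "K": res.params.K if res.params else np.nan,
                "sse": res.sse,
                "rmse": res.rmse,
                "r_squared": res.r_squared,
                "converged": res.converged,
                "x0_policy": res.x0_policy,
                "error": res.error or "",
            }
        )
    return pd.DataFrame(rows)
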