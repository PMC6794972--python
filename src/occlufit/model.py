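"""Logistic model of dentinal tubule occlusion.

The state variable ``X(t)`` is the percentage of tubule area occluded after
``t`` days of brushing with a desensitizing paste.  Occlusion is assumed to
follow the Verhulst logistic law

.. math::

    \\frac{dX}{dt} = r\\, X \\left(1 - \\frac{X}{K}\\right),

where ``r`` (per day) is the occlusion rate and ``K`` (percent) the maximum
attainable occlusion, taken as 100 % unless stated otherwise.  Separation of
variables gives the closed form

.. math::

    X(t) = \\frac{K C e^{r t}}{1 + C e^{r t}}, \\qquad
    C = \\frac{X_0}{K - X_0},

with ``X_0 = X(0)`` the latent pre-brushing occlusion.  This module houses
the model, its closed-form solution, the equilibrium/stability analysis and
the inversion from a target occlusion level to the time needed to reach it.
All computations here are pure; file formats and the command line live in
:mod:`occlufit.io` and :mod:`occlufit.cli`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "LogisticParams",
    "EquilibriumReport",
    "UnreachableThresholdError",
    "logistic_rate",
    "logistic_solution",
    "equilibria_with_stability",
    "time_to_threshold",
    "trajectory_on_grid",
]


class UnreachableThresholdError(ValueError):
    """Raised when a target occlusion level lies at or above the asymptote."""


@dataclass(frozen=True)
class LogisticParams:
    """Parameter triple of one logistic occlusion trajectory.

    Parameters
    ----------
    r
        Occlusion rate, per day.  Fitted values are always >= 0; negative
        values are rejected by the analyses that have no interpretation for
        them (see :func:`equilibria_with_stability`).
    K
        Carrying capacity, percent.  Maximum attainable occlusion; defaults
        to 100 %.
    x0
        Initial occluded fraction ``X(0)`` at ``t = 0`` (pre-brushing),
        percent.  Must lie in ``[0, K]``.
    """

    r: float
    K: float = 100.0
    x0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "K", "x0"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float, np.floating, np.integer)) and math.isfinite(float(v))):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.K <= 0:
            raise ValueError(f"carrying capacity K must be positive, got {self.K}")
        if not 0.0 <= self.x0 <= self.K:
            raise ValueError(f"x0 must lie in [0, K]=[0, {self.K}], got {self.x0}")


@dataclass(frozen=True)
class EquilibriumReport:
    """Equilibria of the occlusion ODE with their stability labels.

    ``equilibria`` holds ``(state value in percent, label)`` pairs where the
    label is ``"stable"``, ``"unstable"`` or ``"neutral"`` (the r = 0
    special case, where the right-hand side vanishes identically and every
    state is an equilibrium; only the canonical pair is listed).
    """

    equilibria: tuple[tuple[float, str], ...]
    note: str = ""


def _validate_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def logistic_rate(x, params: LogisticParams):
    """Instantaneous occlusion rate ``dX/dt = r X (1 - X/K)`` in percent/day.

    Zero exactly at the two equilibria ``X = 0`` and ``X = K``.
    """
    arr = np.asarray(x, dtype=float)
    _validate_finite(arr, "X")
    out = params.r * arr * (1.0 - arr / params.K)
    return out if arr.ndim else float(out)


def logistic_solution(t, params: LogisticParams):
    """Closed-form occlusion percentage ``X(t)``.

    Evaluated through the logistic sigmoid on the log-odds scale,
    ``X(t) = K * expit(logit(x0/K) + r t)``, which is algebraically the
    textbook ratio ``K C e^{rt} / (1 + C e^{rt})`` but stays finite for
    arbitrarily large ``|r t|`` (no ``exp`` overflow).  The boundary states
    ``x0 = 0`` and ``x0 = K`` are fixed points and return constant
    trajectories; ``t = 0`` returns ``x0`` exactly.
    """
    tarr = np.asarray(t, dtype=float)
    _validate_finite(tarr, "t")
    scalar = tarr.ndim == 0
    if params.x0 == 0.0 or params.x0 == params.K:
        out = np.full_like(tarr, params.x0, dtype=float)
        return float(out) if scalar else out
    out = params.K * expit(logit(params.x0 / params.K) + params.r * tarr)
    # pin t = 0 to the exact initial value (expit/logit round-trip can be
    # off by one ulp)
    out = np.where(tarr == 0.0, params.x0, out)
    return float(out) if scalar else out


def equilibria_with_stability(params: LogisticParams) -> EquilibriumReport:
    """Equilibria of the occlusion ODE and their local stability.

    The right-hand side ``f(X) = r X (1 - X/K)`` vanishes at ``X = 0`` and
    ``X = K``; stability follows the sign of ``f'(X) = r (1 - 2X/K)`` at
    each root.  For any ``r > 0`` this yields ``{(0, unstable),
    (K, stable)}``: trajectories started in ``(0, K]`` converge to full
    occlusion ``K`` and cannot decay to zero.

    ``r = 0`` is reported as the documented degenerate case (``f`` is
    identically zero, every state neutrally stable); ``r < 0`` has no
    interpretation for a remineralization process and is refused.
    """
    if params.r < 0:
        raise ValueError(
            "negative occlusion rates have no interpretation here; r must be >= 0"
        )
    if params.r == 0.0:
        return EquilibriumReport(
            equilibria=((0.0, "neutral"), (params.K, "neutral")),
            note="r = 0: dX/dt vanishes identically, every state is neutrally stable",
        )

    def fprime(x: float) -> float:
        return params.r * (1.0 - 2.0 * x / params.K)

    labels = tuple(
        (x, "stable" if fprime(x) < 0 else "unstable") for x in (0.0, params.K)
    )
    return EquilibriumReport(equilibria=labels)


def time_to_threshold(params: LogisticParams, threshold: float) -> float:
    """Days needed for the trajectory to reach a target occlusion level.

    Closed-form inversion of the logistic solution,

    ``t = (1/r) * ln[ threshold (K - x0) / (x0 (K - threshold)) ]``,

    so that ``logistic_solution(t) == threshold`` to floating-point
    accuracy.  The carrying capacity is an asymptote, hence thresholds at or
    above ``K`` are unreachable in finite time.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if params.r <= 0:
        raise ValueError("time_to_threshold requires a positive occlusion rate r")
    if threshold >= params.K:
        raise UnreachableThresholdError(
            f"threshold {threshold} >= carrying capacity {params.K}: "
            "the trajectory only approaches K asymptotically"
        )
    if threshold == params.x0:
        return 0.0
    if threshold < params.x0:
        raise ValueError(
            f"threshold {threshold} below the initial value x0={params.x0}; "
            "an increasing trajectory never returns there"
        )
    if params.x0 == 0.0:
        raise UnreachableThresholdError(
            "x0 = 0 is a fixed point; no positive threshold is ever reached"
        )
    num = threshold * (params.K - params.x0)
    den = params.x0 * (params.K - threshold)
    return math.log(num / den) / params.r


def trajectory_on_grid(params: LogisticParams, days: Sequence[float]) -> np.ndarray:
    """Vectorized closed-form trajectory on a grid of observation days."""
    grid = np.asarray(days, dtype=float)
    if grid.size == 0:
        raise ValueError("days grid must be non-empty")
    _validate_finite(grid, "days")
    return np.asarray(logistic_solution(grid, params), dtype=float)
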