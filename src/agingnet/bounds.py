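"""Closed-form bounds on the mean-field mortality rate.

Integrating the damage-fraction ODE between crude rate estimates yields
explicit lower and upper envelopes for m(t):

    lower:  m(t) >~ (g0^2 t / D) * exp(r+ g0 t / D),  D = 1 + ((R+1)/R) g0 t
    upper:  m(t) <~ (2 g0 / r+) * L * e^L,            L = -ln(1 - r+ g0 t)

with g0 = gamma0. The upper bound comes from the series sum_k (r+ g0 t)^k / k,
which converges only for r+ g0 t < 1; it is summed here in its -ln closed
form. In the small-t regime both reduce to (1 resp. 2) * g0^2 t e^{r+ g0 t},
which gives the explicit Gompertz-parameter approximations
beta ~ r+ gamma0 and t_lo*g0^2 <~ alpha <~ 2*t_hi*g0^2 on a window [t_lo, t_hi].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gompertz import HazardCurve, fit_gompertz
from .parameters import RateParameters

_DIVERGENCE_SENTINEL = 1e10  # per year; values above are reported as +inf


def lower_bound_m(t, params: RateParameters) -> np.ndarray:
    """Lower envelope of the mortality rate at ages ``t`` (years)."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("ages must be nonnegative")
    g0 = params.gamma0
    denom = 1.0 + (params.R + 1.0) / params.R * g0 * t
    return g0**2 * t / denom * np.exp(params.r_plus * g0 * t / denom)


def upper_bound_m(t, params: RateParameters) -> np.ndarray:
    """Upper envelope of the mortality rate; only valid for r+ gamma0 t < 1."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("ages must be nonnegative")
    x = params.r_plus * params.gamma0 * t
    if (x >= 1.0).any():
        bad = float(t[x >= 1.0][0])
        raise ValueError(
            f"upper bound invalid at t={bad:.4g} y: requires r_plus*gamma0*t < 1"
        )
    L = -np.log1p(-x)
    return 2.0 * params.gamma0 / params.r_plus * L * np.exp(L)


@dataclass(frozen=True)
class BoundCurves:
    """Lower/upper mortality-rate envelopes on an age grid, with validity flags
    for the upper bound (series radius and divergence sentinel)."""

    ages: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    validity: np.ndarray


def bound_curves(ages, params: RateParameters) -> BoundCurves:
    """Evaluate both bounds on a grid; invalid upper-bound ages get +inf."""
    ages = np.asarray(ages, dtype=float)
    lower = lower_bound_m(ages, params)
    x = params.r_plus * params.gamma0 * ages
    valid = x < 1.0
    upper = np.full_like(ages, np.inf)
    if valid.any():
        upper[valid] = upper_bound_m(ages[valid], params)
    diverged = valid & (upper > _DIVERGENCE_SENTINEL)
    upper[diverged] = np.inf
    valid = valid & ~diverged
    return BoundCurves(ages=ages, lower=lower, upper=upper, validity=valid)


def approximate_gompertz_parameters(
    params: RateParameters, window: tuple[float, float] = (40.0, 80.0)
) -> tuple[float, tuple[float, float]]:
    """Explicit small-t Gompertz parameters: beta ~ r+ gamma0, and the
    ln(alpha) sandwich (ln(t_lo g0^2), ln(2 t_hi g0^2)) over the window.

    For the canonical [40, 80]-year window this is the 40 g0^2 .. 160 g0^2
    sandwich, a factor 4 wide.
    """
    t_lo, t_hi = window
    if not 0 < t_lo < t_hi:
        raise ValueError("window must satisfy 0 < t_lo < t_hi")
    g0 = params.gamma0
    beta = params.r_plus * g0
    return beta, (float(np.log(t_lo * g0**2)), float(np.log(2.0 * t_hi * g0**2)))


def fit_bound_slopes(
    params: RateParameters, window: tuple[float, float] = (40.0, 80.0)
) -> tuple[float, float]:
    """OLS slopes of ln(lower bound) and ln(upper bound) at integer years
    inside the (inclusive) window."""
    ages = np.arange(np.ceil(window[0]), np.floor(window[1]) + 1.0)
    low = fit_gompertz(
        HazardCurve(ages=ages, rates=lower_bound_m(ages, params), source="meanfield"),
        window,
    )
    up = fit_gompertz(
        HazardCurve(ages=ages, rates=upper_bound_m(ages, params), source="meanfield"),
        window,
    )
    return low.beta, up.beta
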