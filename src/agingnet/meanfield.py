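"""Mean-field reduction of the aging process and the approximate mortality rate.

Replacing every node's neighbour damage fraction by the population damage
fraction p(t), and aggregating states by the mortality-node pair into
other / pre-death / death classes, yields two coupled ODEs on the
dimensionless time scale s = gamma0 * t:

    dp*/ds  = (1 - p*) A+*(p*) - p*  A-*(p*),        p*(0)  = 0
    dchi*/ds = (1 - chi*) 2 A+*(p*) - chi* A-*(p*),  chi*(0) = 0

with scaled rates A+*(p) = e^{r+ p}, A-*(p) = e^{-r- p}/R. Here p*(s) is
the expected damage fraction and chi*(s) the probability of sitting in the
pre-death class conditional on survival. The approximate mortality rate is

    m*(s) = gamma0 * A+*(p*(s)) * chi*(s)   [per year],  m(t) = m*(gamma0 t).

Both curves increase strictly to fixed points p-dagger and
chi-dagger = 2 p-dagger / (1 + p-dagger), and satisfy the strict sandwich
p* < chi* < 2 p* for all s > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import bisect

from .parameters import RateParameters

# survival weight exp(-H) is negligible below this cumulative hazard
_HAZARD_CUTOFF = 23.0


class SolverError(RuntimeError):
    """The ODE integrator failed to meet its tolerance."""


class GridExtentError(ValueError):
    """The solved grid does not extend far enough for the requested quantity."""


@dataclass(frozen=True)
class MeanFieldSolution:
    """Mean-field solution on a uniform macroscopic grid.

    ``m_star`` is in 1/year; ``cum_hazard`` is the dimensionless
    cumulative hazard integral of A+*(p*) chi* over s. ``dense`` is the
    solver's dense-output interpolant for (p*, chi*, cum_hazard),
    evaluable at any s in [0, s_max].
    """

    params: RateParameters
    s_grid: np.ndarray
    p_star: np.ndarray
    chi_star: np.ndarray
    m_star: np.ndarray
    cum_hazard: np.ndarray
    dense: object

    @property
    def s_max(self) -> float:
        return float(self.s_grid[-1])

    def at(self, s):
        """(p*, chi*) at arbitrary macroscopic times ``s``."""
        out = self.dense(np.asarray(s, dtype=float))
        return out[0], out[1]

    def hazard_at_ages(self, t_years):
        """Mortality rate m(t) [1/year] at ages ``t_years`` via the dense interpolant."""
        t = np.asarray(t_years, dtype=float)
        p, chi = self.at(self.params.gamma0 * t)
        return self.params.gamma0 * np.exp(self.params.r_plus * p) * chi


def solve_meanfield(
    params: RateParameters,
    s_max: float = 0.15,
    grid_points: int = 3001,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> MeanFieldSolution:
    """Solve the coupled mean-field system on s in [0, s_max].

    Adaptive Runge–Kutta with dense output, resampled to a uniform grid of
    ``grid_points`` points. A third component accumulates the cumulative
    hazard, used by :func:`damage_fraction_at_death`.
    """
    if s_max <= 0:
        raise ValueError("s_max must be positive")
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    rp, rm, R = params.r_plus, params.r_minus, params.R

    def rhs(s, y):
        p, chi, _ = y
        ap = np.exp(rp * p)
        am = np.exp(-rm * p) / R
        return ((1.0 - p) * ap - p * am, (1.0 - chi) * 2.0 * ap - chi * am, ap * chi)

    sol = solve_ivp(
        rhs,
        (0.0, s_max),
        (0.0, 0.0, 0.0),
        method="RK45",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise SolverError(f"integration failed at s={sol.t[-1]:.6g}: {sol.message}")

    s = np.linspace(0.0, s_max, grid_points)
    p, chi, cum_h = sol.sol(s)
    p = np.clip(p, 0.0, 1.0)
    chi = np.clip(chi, 0.0, 1.0)
    m = params.gamma0 * np.exp(rp * p) * chi
    return MeanFieldSolution(
        params=params,
        s_grid=s,
        p_star=p,
        chi_star=chi,
        m_star=m,
        cum_hazard=cum_h,
        dense=sol.sol,
    )


def mortality_rate_in_years(
    sol: MeanFieldSolution, params: RateParameters | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale the solution grid to ages: t = s/gamma0, m(t) = m*(gamma0 t)."""
    params = params or sol.params
    return sol.s_grid / params.gamma0, sol.m_star


@dataclass(frozen=True)
class FixedPoints:
    """Limiting damage fraction and pre-death occupancy."""

    p_dagger: float
    chi_dagger: float


def fixed_points(params: RateParameters, xtol: float = 1e-12) -> FixedPoints:
    """Solve p = 1/(1 + e^{-(r+ + r-) p}/R) by bisection; chi follows in closed form."""
    rsum = params.r_plus + params.r_minus
    R = params.R

    def g(p):
        return p - 1.0 / (1.0 + np.exp(-rsum * p) / R)

    lo, hi = 1e-15, 1.0 - 1e-15
    if not (g(lo) < 0 < g(hi)):
        raise AssertionError("fixed-point bracket failed; parameters out of range")
    p_dag = bisect(g, lo, hi, xtol=xtol)
    return FixedPoints(p_dagger=float(p_dag), chi_dagger=float(2 * p_dag / (1 + p_dag)))


def chi_star_closed_form(
    s_grid: np.ndarray, p_star: np.ndarray, params: RateParameters
) -> np.ndarray:
    """Pre-death occupancy from its integral representation.

    Given p* on a grid, chi* solves a linear ODE with integrating factor
    exp(-int (2A+* + A-*)); this evaluates the resulting double integral
    step by step with an exponential (integrating-factor) rule, which stays
    accurate even where the rates saturate and the explicit double
    integral would overflow.
    """
    s = np.asarray(s_grid, dtype=float)
    p = np.asarray(p_star, dtype=float)
    if s.size < 10:
        raise ValueError("grid too coarse: need at least 10 points")
    a = 2.0 * params.a_plus_star(p)               # inflow rate into pre-death
    b = a + params.a_minus_star(p)                # total relaxation rate
    chi = np.zeros_like(s)
    for k in range(s.size - 1):
        h = s[k + 1] - s[k]
        a_bar = 0.5 * (a[k] + a[k + 1])
        b_bar = 0.5 * (b[k] + b[k + 1])
        decay = np.exp(-b_bar * h)
        chi[k + 1] = chi[k] * decay + (a_bar / b_bar) * (1.0 - decay)
    return chi


@dataclass(frozen=True)
class DamageAtDeath:
    """Expected damage fraction at the moment of death, with the survival
    mass beyond the grid truncation as an error bound."""

    value: float
    truncation_error: float


def damage_fraction_at_death(
    params: RateParameters, sol: MeanFieldSolution, refine: int = 20001
) -> DamageAtDeath:
    """Expected fraction of damaged nodes at death, by quadrature.

    Integrates p(t) against the death density m(t) exp(-int_0^t m), written
    on the macroscopic scale so gamma0 cancels. Requires the solved grid to
    carry essentially all the survival mass (cumulative hazard > 23 at the
    grid end, i.e. survival < 1e-10).
    """
    h_end = float(sol.cum_hazard[-1])
    if h_end < _HAZARD_CUTOFF:
        raise GridExtentError(
            f"cumulative hazard at s_max is {h_end:.3g} < {_HAZARD_CUTOFF}; "
            f"re-solve with s_max > {sol.s_max * 1.5:.3g}"
        )
    s = np.linspace(0.0, sol.s_max, refine)
    p, chi, cum_h = sol.dense(s)
    hazard = np.exp(params.r_plus * p) * chi          # dimensionless m*(s)/gamma0
    weight = np.exp(-np.clip(cum_h, 0.0, 700.0))
    value = float(np.trapezoid(hazard * p * weight, s))
    return DamageAtDeath(value=value, truncation_error=float(np.exp(-min(h_end, 700.0))))
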