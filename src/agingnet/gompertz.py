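"""Hazard estimation from lifetimes and Gompertz-law fitting.

The Gompertz law m(t) ~ alpha * e^{beta t} is fitted by ordinary least
squares of ln m(t) against age over a window. Hazards from simulated
cohorts are estimated with the occurrence/exposure rate: deaths per
person-year at risk within each age bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HazardCurve:
    """Hazard rate per year on a strictly increasing age grid."""

    ages: np.ndarray
    rates: np.ndarray
    source: str = "file"

    def __post_init__(self) -> None:
        if not (np.diff(self.ages) > 0).all():
            raise ValueError("ages must be strictly increasing")
        finite = self.rates[np.isfinite(self.rates)]
        if (finite < 0).any():
            raise ValueError("hazard rates must be nonnegative")


@dataclass(frozen=True)
class GompertzFit:
    """Log-linear hazard fit m(t) = alpha * e^{beta t} over an age window."""

    alpha: float
    beta: float
    r_squared: float
    mse: float
    window: tuple[float, float]
    n_points: int

    @property
    def intercept(self) -> float:
        return float(np.log(self.alpha))


def hazard_from_lifetimes(
    lifetimes: Sequence[float], bin_width: float = 1.0, source: str = "simulation"
) -> HazardCurve:
    """Occurrence/exposure hazard estimate on age bins of width ``bin_width``.

    Each bin's rate is (deaths in bin) / (person-years lived in the bin by
    everyone still alive when it starts). Bins beyond the last death are
    dropped; returned ages are bin midpoints.
    """
    taus = np.asarray(lifetimes, dtype=float)
    if taus.size == 0:
        raise ValueError("need at least one lifetime")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(taus.max() / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    deaths, _ = np.histogram(taus, bins=edges)
    # exposure in bin [e, e+w): sum over individuals of clip(tau - e, 0, w)
    exposure = np.array([np.clip(taus - e, 0.0, bin_width).sum() for e in edges[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(exposure > 0, deaths / exposure, np.nan)
    mids = edges[:-1] + bin_width / 2.0
    return HazardCurve(ages=mids, rates=rates, source=source)


def fit_gompertz(curve: HazardCurve, window: tuple[float, float]) -> GompertzFit:
    """OLS of ln m(t) against t at the curve's sample ages inside the window.

    Window endpoints are inclusive. Ages with zero, missing or non-finite
    hazard are excluded (with a logged warning) rather than floored, since
    flooring would bias the intercept. Requires at least 3 usable points.
    """
    lo, hi = window
    in_window = (curve.ages >= lo) & (curve.ages <= hi)
    t = curve.ages[in_window]
    m = curve.rates[in_window]
    usable = np.isfinite(m) & (m > 0)
    if (~usable).any():
        log.warning(
            "excluding %d of %d window points with zero/missing hazard",
            int((~usable).sum()),
            t.size,
        )
    t, m = t[usable], m[usable]
    if t.size < 3:
        raise ValueError(f"need >= 3 usable points in window {window}, have {t.size}")
    res = stats.linregress(t, np.log(m))
    residuals = np.log(m) - (res.intercept + res.slope * t)
    return GompertzFit(
        alpha=float(np.exp(res.intercept)),
        beta=float(res.slope),
        r_squared=float(res.rvalue**2),
        mse=float(np.mean(residuals**2)),
        window=(float(lo), float(hi)),
        n_points=int(t.size),
    )


def gompertz_survival(fit: GompertzFit, t) -> np.ndarray:
    """Survival s(t) implied by the fit, normalised so s(0) = 1.

    s(t) = exp[(alpha/beta)(1 - e^{beta t})]; the beta -> 0 limit is the
    exponential survival exp(-alpha t).
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("ages must be nonnegative")
    if fit.beta == 0.0:
        return np.exp(-fit.alpha * t)
    return np.exp((fit.alpha / fit.beta) * (1.0 - np.exp(fit.beta * t)))


def meanfield_hazard_curve(sol, max_age: float | None = None) -> HazardCurve:
    """Mean-field mortality rate sampled at integer years (the fitting grid)."""
    max_age = max_age if max_age is not None else sol.s_max / sol.params.gamma0
    ages = np.arange(0.0, np.floor(max_age) + 1.0)
    ages = ages[1:]  # m(0) = 0, unusable on a log scale
    return HazardCurve(ages=ages, rates=sol.hazard_at_ages(ages), source="meanfield")
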