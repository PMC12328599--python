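"""Poisson behaviour of superposed sparse renewal processes.

The exponential-clock dynamics of single health indicators is justified by
a classical limit: merging many independent, individually rare point
processes produces a process indistinguishable from a Poisson process,
regardless of the constituents' interarrival law. This module demonstrates
that empirically: it simulates superpositions of stationary renewal
processes and runs Poisson diagnostics (dispersion index of subinterval
counts, and a Kolmogorov–Smirnov test of interarrivals against the
exponential law).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

SUPPORTED_LAWS = ("exponential", "uniform", "gamma", "deterministic")


@dataclass(frozen=True)
class SuperpositionSpec:
    """``k`` i.i.d. stationary renewal constituents with total mean rate
    ``rate`` (each contributes rate/k) observed on [0, horizon]."""

    k: int
    law: str
    rate: float
    horizon: float
    gamma_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.law not in SUPPORTED_LAWS:
            raise ValueError(
                f"unsupported interarrival law {self.law!r}; choose from {SUPPORTED_LAWS}"
            )
        if self.k < 1 or self.rate <= 0 or self.horizon <= 0:
            raise ValueError("k >= 1 and rate, horizon > 0 required")


def _interarrivals(law: str, mean: float, size: int, rng, shape: float) -> np.ndarray:
    if law == "exponential":
        return rng.exponential(mean, size)
    if law == "uniform":
        return rng.uniform(0.0, 2.0 * mean, size)
    if law == "gamma":
        return rng.gamma(shape, mean / shape, size)
    return np.full(size, mean)  # deterministic


def _equilibrium_delay(law: str, mean: float, rng, shape: float) -> float:
    """First arrival of a stationary renewal process (forward recurrence time).

    Sampled as U * L where L is a length-biased interarrival interval — the
    inspection-paradox construction of the equilibrium distribution.
    """
    u = rng.random()
    if law == "exponential":
        return rng.exponential(mean)  # memoryless: no bias needed
    if law == "uniform":
        # length-biased density x/(2 mean^2) on (0, 2 mean) -> inverse-CDF sqrt
        return u * 2.0 * mean * np.sqrt(rng.random())
    if law == "gamma":
        return u * rng.gamma(shape + 1.0, mean / shape)
    return u * mean  # deterministic


def simulate_superposition(spec: SuperpositionSpec, seed: int) -> np.ndarray:
    """Merged, sorted event times of the superposition on [0, horizon]."""
    rng = np.random.default_rng(seed)
    mean = spec.k / spec.rate  # per-constituent mean interarrival time
    events: list[np.ndarray] = []
    for _ in range(spec.k):
        t = _equilibrium_delay(spec.law, mean, rng, spec.gamma_shape)
        times = []
        while t <= spec.horizon:
            times.append(t)
            t += float(_interarrivals(spec.law, mean, 1, rng, spec.gamma_shape)[0])
        if times:
            events.append(np.array(times))
    if not events:
        return np.empty(0)
    return np.sort(np.concatenate(events))


@dataclass(frozen=True)
class PoissonDiagnostics:
    """Dispersion index of subinterval counts (1 for Poisson) and KS statistic
    of interarrival times against the exponential with the empirical mean."""

    dispersion_index: float
    ks_statistic: float
    ks_pvalue: float


def poisson_diagnostics(
    events: np.ndarray, n_subintervals: int, horizon: float | None = None
) -> PoissonDiagnostics:
    events = np.asarray(events, dtype=float)
    if events.size < 10:
        raise ValueError("need at least 10 events for diagnostics")
    horizon = float(horizon) if horizon is not None else float(events[-1])
    counts, _ = np.histogram(events, bins=np.linspace(0.0, horizon, n_subintervals + 1))
    dispersion = counts.var() / counts.mean()
    inter = np.diff(events)
    ks = stats.kstest(inter, "expon", args=(0.0, inter.mean()))
    return PoissonDiagnostics(
        dispersion_index=float(dispersion),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )
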