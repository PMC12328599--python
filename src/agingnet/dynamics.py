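"""Exact stochastic simulation of the binary-state aging process.

Each node of a :class:`~agingnet.network.HealthNetwork` is healthy (0) or
damaged (1) and flips at rates driven by the fraction of damaged
neighbours. Death is absorption into the set of states where both
mortality nodes are damaged; a lifetime is the first hitting time of that
set starting from the all-healthy state.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _gillespie
from .network import HealthNetwork
from .parameters import RateParameters

DEFAULT_EVENT_CAP = 10**8


class StateClass(str, enum.Enum):
    """Classification of a network state by the two mortality-node bits."""

    OTHER = "other"        # (0,0)
    PREDEATH = "predeath"  # (1,0) or (0,1)
    DEATH = "death"        # (1,1)


@dataclass
class NetworkState:
    """Bit vector of node states plus the current age in years."""

    bits: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("states must be 0 (healthy) or 1 (damaged)")


@dataclass(frozen=True)
class LifetimeRecord:
    """One simulated individual.

    ``trajectory`` is a pair of arrays (event times in years, damage
    fraction after each event), or ``None`` if recording was disabled.
    """

    tau: float
    damage_at_death: float
    trajectory: tuple[np.ndarray, np.ndarray] | None = None


class EventCapExceeded(RuntimeError):
    """The per-lifetime event cap was hit before death was reached."""


def neighbour_damage_fraction(state: NetworkState, net: HealthNetwork, i: int) -> float:
    """Fraction of node ``i``'s neighbours that are damaged."""
    nbrs = net.neighbours(i)
    if nbrs.size == 0:
        raise ValueError(f"node {i} has no neighbours")
    return float(state.bits[nbrs].mean())


def transition_rates(f: float, params: RateParameters) -> tuple[float, float]:
    """(damage rate, recovery rate) per year at neighbour damage fraction ``f``."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"damage fraction f={f} outside [0,1]")
    return params.rate_up(f), params.rate_down(f)


def classify_state(state: NetworkState, net: HealthNetwork) -> StateClass:
    m1, m2 = net.mortality_nodes
    z1, z2 = int(state.bits[m1]), int(state.bits[m2])
    if z1 and z2:
        return StateClass.DEATH
    if z1 or z2:
        return StateClass.PREDEATH
    return StateClass.OTHER


def predeath_exit_probability(
    state: NetworkState, net: HealthNetwork, params: RateParameters
) -> float:
    """Probability that the next event out of a pre-death state is fatal.

    With exactly one mortality node damaged, the fatal event is the healthy
    mortality node flipping to damaged; its rate divided by the total event
    rate gives the exit probability F(z).
    """
    if classify_state(state, net) is not StateClass.PREDEATH:
        raise ValueError("state is not in the pre-death class")
    m1, m2 = net.mortality_nodes
    healthy_mortality = m2 if state.bits[m1] == 1 else m1

    total = 0.0
    for i in range(net.n):
        f = neighbour_damage_fraction(state, net, i)
        total += params.rate_down(f) if state.bits[i] else params.rate_up(f)
    fatal = params.rate_up(neighbour_damage_fraction(state, net, healthy_mortality))
    return fatal / total


def simulate_lifetime(
    net: HealthNetwork,
    params: RateParameters,
    seed: int,
    record: bool = True,
    max_events: int = DEFAULT_EVENT_CAP,
) -> LifetimeRecord:
    """Simulate one lifetime from the all-healthy state (exact SSA).

    Holding times are exponential at the total rate; the flipping node is
    chosen proportionally to per-node rates; only the flipped node and its
    neighbours have their rates updated. Stops at the first state with both
    mortality nodes damaged.
    """
    tau, p_death, times, phat, n_events, status = _gillespie.simulate_lifetime_kernel(
        net.indptr,
        net.indices,
        net.mortality_nodes[0],
        net.mortality_nodes[1],
        params.r_plus,
        params.r_minus,
        params.gamma0,
        params.R,
        _as_kernel_seed(seed),
        max_events,
        record,
    )
    if status == _gillespie.EVENT_CAP:
        raise EventCapExceeded(
            f"no death after {n_events} events (cap {max_events}); "
            "check the rate parameters"
        )
    trajectory = (times, phat) if record else None
    return LifetimeRecord(tau=float(tau), damage_at_death=float(p_death), trajectory=trajectory)


def cohort_seeds(master_seed: int, n_samples: int) -> np.ndarray:
    """Independent per-replicate kernel seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([s.generate_state(1)[0] % (2**31) for s in ss.spawn(n_samples)])


def simulate_cohort(
    net: HealthNetwork,
    params: RateParameters,
    n_samples: int,
    seed: int,
    record: bool = False,
    max_events: int = DEFAULT_EVENT_CAP,
    progress_every: int | None = None,
) -> list[LifetimeRecord]:
    """Independent replicate lifetimes with seeds derived from ``seed``."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seeds = cohort_seeds(seed, n_samples)
    records: list[LifetimeRecord] = []
    for idx, s in enumerate(seeds):
        try:
            records.append(
                simulate_lifetime(net, params, int(s), record=record, max_events=max_events)
            )
        except EventCapExceeded as exc:
            raise EventCapExceeded(f"replicate {idx}: {exc}") from exc
        if progress_every and (idx + 1) % progress_every == 0:
            import sys

            print(f"simulated {idx + 1}/{n_samples} lifetimes", file=sys.stderr)
    return records


def _as_kernel_seed(seed: int) -> int:
    # numba's np.random.seed wants a nonnegative 32-bit integer
    return int(seed) % (2**31)


def lifetimes(records: Sequence[LifetimeRecord]) -> np.ndarray:
    return np.array([r.tau for r in records])
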