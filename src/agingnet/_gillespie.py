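"""Numba kernel for the exact event-driven simulation of the aging process.

Per-node flip rates depend only on the current state, so the process is a
continuous-time Markov jump process and the classical stochastic simulation
algorithm is exact: exponential holding time at the total rate, next event
chosen proportionally to per-node rates. Rates are kept in a Fenwick
(binary indexed) tree so that both the rate update after a flip and the
proportional node selection cost O(log n); a flip only touches the flipped
node and its neighbours.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
EVENT_CAP = 1


@njit(cache=True)
def _tree_update(tree, i, delta):
    # 1-based Fenwick point update
    i += 1
    while i < tree.size:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _tree_total(tree, n):
    total = 0.0
    i = n
    while i > 0:
        total += tree[i]
        i -= i & (-i)
    return total


@njit(cache=True)
def _tree_sample(tree, n, target):
    """Smallest index i with prefix_sum(i) > target (0-based node id)."""
    idx = 0
    bitmask = 1
    while bitmask * 2 <= n:
        bitmask *= 2
    while bitmask > 0:
        nxt = idx + bitmask
        if nxt <= n and tree[nxt] <= target:
            idx = nxt
            target -= tree[nxt]
        bitmask //= 2
    if idx >= n:  # guard against roundoff at the right edge
        idx = n - 1
    return idx


@njit(cache=True, inline="always")
def _node_rate(damaged, ndmg, deg, r_plus, r_minus, gamma0, R):
    f = ndmg / deg
    if damaged:
        return gamma0 / R * np.exp(-r_minus * f)
    return gamma0 * np.exp(r_plus * f)


@njit(cache=True)
def simulate_lifetime_kernel(
    indptr,
    indices,
    m1,
    m2,
    r_plus,
    r_minus,
    gamma0,
    R,
    seed,
    max_events,
    record,
):
    """Run one lifetime from the all-healthy state until both mortality nodes
    are damaged.

    Returns (tau, damage_at_death, times, phat, n_events, status). When
    ``record`` is True, ``times``/``phat`` hold the event times and the
    damage fraction after every event (including the fatal one).
    """
    n = indptr.size - 1
    np.random.seed(seed)

    bits = np.zeros(n, np.uint8)
    ndmg = np.zeros(n, np.int64)
    deg = np.empty(n, np.float64)
    for i in range(n):
        deg[i] = indptr[i + 1] - indptr[i]

    tree = np.zeros(n + 1, np.float64)
    for i in range(n):
        _tree_update(tree, i, gamma0)  # all-healthy: rate_up at f=0

    cap = 1024 if record else 1
    times = np.empty(cap, np.float64)
    phat = np.empty(cap, np.float64)

    t = 0.0
    n_damaged = 0
    n_events = 0
    status = EVENT_CAP
    tau = np.nan

    while n_events < max_events:
        total = _tree_total(tree, n)
        t += np.random.exponential(1.0) / total
        k = _tree_sample(tree, n, np.random.random() * total)
        n_events += 1

        was_damaged = bits[k] == 1
        bits[k] = 0 if was_damaged else 1
        n_damaged += -1 if was_damaged else 1

        new_rate = _node_rate(bits[k] == 1, ndmg[k], deg[k], r_plus, r_minus, gamma0, R)
        old_rate = _node_rate(was_damaged, ndmg[k], deg[k], r_plus, r_minus, gamma0, R)
        _tree_update(tree, k, new_rate - old_rate)

        dn = -1 if was_damaged else 1
        for j in indices[indptr[k] : indptr[k + 1]]:
            old_j = _node_rate(bits[j] == 1, ndmg[j], deg[j], r_plus, r_minus, gamma0, R)
            ndmg[j] += dn
            new_j = _node_rate(bits[j] == 1, ndmg[j], deg[j], r_plus, r_minus, gamma0, R)
            _tree_update(tree, j, new_j - old_j)

        if record:
            if n_events > cap:
                new_cap = cap * 2
                new_times = np.empty(new_cap, np.float64)
                new_phat = np.empty(new_cap, np.float64)
                new_times[:cap] = times
                new_phat[:cap] = phat
                times = new_times
                phat = new_phat
                cap = new_cap
            times[n_events - 1] = t
            phat[n_events - 1] = n_damaged / n

        if bits[m1] == 1 and bits[m2] == 1:
            tau = t
            status = OK
            break

    return tau, n_damaged / n, times[:n_events], phat[:n_events], n_events, status
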