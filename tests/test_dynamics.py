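import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import ks_1samp

import agingnet as ag
from agingnet.dynamics import (
    NetworkState,
    StateClass,
    classify_state,
    neighbour_damage_fraction,
    predeath_exit_probability,
    simulate_cohort,
    simulate_lifetime,
    transition_rates,
)


@pytest.fixture
def fast_params() -> ag.RateParameters:
    """Order-one rates so small-network lifetimes are cheap to simulate."""
    return ag.RateParameters(r_plus=2.0, r_minus=1.0, gamma0=1.0, R=1.0)


class TestLocalQuantities:
    def test_transition_rates_at_zero_damage(self):
        p = ag.RateParameters(r_plus=3.0, r_minus=2.0, gamma0=0.1, R=2.0)
        up, down = transition_rates(0.0, p)
        assert up == pytest.approx(0.1)
        assert down == pytest.approx(0.05)

    def test_symmetric_rates_when_r_is_one(self):
        p = ag.RateParameters(r_plus=1.0, r_minus=1.0, gamma0=0.3, R=1.0)
        up, down = transition_rates(0.0, p)
        assert up == down

    def test_fully_damaged_neighbourhood_rate(self):
        # gamma0 * e^{r+} at f=1 for the reference damage exponent
        p = ag.RateParameters(r_plus=10.27, r_minus=6.5, gamma0=0.00113, R=1.5)
        up, _ = transition_rates(1.0, p)
        assert up == pytest.approx(0.00113 * np.exp(10.27))
        assert up == pytest.approx(32.6, rel=0.01)

    def test_rate_domain_error(self, fast_params):
        with pytest.raises(ValueError):
            transition_rates(1.5, fast_params)

    @pytest.mark.parametrize(
        "bits, expected",
        [((0, 0, 0, 0, 0), 0.0), ((0, 1, 1, 1, 1), 1.0), ((0, 1, 0, 0, 0), 0.25)],
    )
    def test_neighbour_damage_fraction(self, bits, expected):
        net = ag.HealthNetwork.from_edges(5, [(0, i) for i in range(1, 5)])
        state = NetworkState(bits=np.array(bits))
        assert neighbour_damage_fraction(state, net, 0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "z12, expected",
        [
            ((0, 0), StateClass.OTHER),
            ((1, 0), StateClass.PREDEATH),
            ((0, 1), StateClass.PREDEATH),
            ((1, 1), StateClass.DEATH),
        ],
    )
    def test_state_classification(self, small_network, z12, expected):
        bits = np.array([*z12, 0])
        assert classify_state(NetworkState(bits=bits), small_network) is expected


class TestPredeathExitProbability:
    def test_equal_rates_limit_on_triangle(self, small_network):
        # with vanishing exponents and R=1 all three events are equally likely
        eps = 1e-12
        p = ag.RateParameters(r_plus=eps, r_minus=eps, gamma0=1.0, R=1.0)
        state = NetworkState(bits=np.array([1, 0, 0]))
        assert predeath_exit_probability(state, small_network, p) == pytest.approx(
            1.0 / 3.0, abs=1e-9
        )

    def test_two_node_network_closed_form(self, pair_network, fast_params):
        # z = (1,0): the fatal event is node 2 damaging at f = 1; the only
        # competing event is node 1 recovering at its own neighbour fraction
        # f = 0 (its sole neighbour, node 2, is healthy)
        state = NetworkState(bits=np.array([1, 0]))
        ap = fast_params.rate_up(1.0)
        am = fast_params.rate_down(0.0)
        assert predeath_exit_probability(state, pair_network, fast_params) == pytest.approx(
            ap / (ap + am)
        )

    def test_strictly_between_zero_and_one(self, generated_network, ref_params, rng):
        for _ in range(5):
            bits = (rng.random(generated_network.n) < 0.3).astype(np.uint8)
            m1, m2 = generated_network.mortality_nodes
            bits[m1], bits[m2] = 1, 0
            f = predeath_exit_probability(
                NetworkState(bits=bits), generated_network, ref_params
            )
            assert 0.0 < f < 1.0

    def test_contract_error_outside_predeath(self, small_network, fast_params):
        with pytest.raises(ValueError):
            predeath_exit_probability(
                NetworkState(bits=np.zeros(3)), small_network, fast_params
            )


class TestSimulateLifetime:
    def test_death_state_at_absorption(self, small_network, fast_params):
        rec = simulate_lifetime(small_network, fast_params, seed=5)
        assert rec.tau > 0
        times, phat = rec.trajectory
        assert (np.diff(times) > 0).all()
        assert times[-1] == pytest.approx(rec.tau)
        assert phat[-1] == pytest.approx(rec.damage_at_death)
        # at death at least the two mortality nodes are damaged
        assert rec.damage_at_death >= 2 / small_network.n

    def test_lifetime_distribution_matches_matrix_exponential(
        self, pair_network, fast_params
    ):
        """Gillespie lifetimes on the 2-node network against the 4-state
        CTMC solved by the matrix exponential (Kolmogorov forward equations)."""
        recs = simulate_cohort(pair_network, fast_params, 10_000, seed=42)
        taus = np.array([r.tau for r in recs])

        up0, down0 = transition_rates(0.0, fast_params)
        up1, down1 = transition_rates(1.0, fast_params)
        # states 00, 10, 01, 11; 11 absorbing
        q = np.zeros((4, 4))
        q[0, 1] = q[0, 2] = up0
        q[1, 0] = q[2, 0] = down0
        q[1, 3] = q[2, 3] = up1
        np.fill_diagonal(q, -q.sum(axis=1))

        def cdf(t):
            return np.array([expm(q * ti)[0, 3] for ti in np.atleast_1d(t)])

        res = ks_1samp(taus, cdf)
        assert res.statistic < 0.02

    def test_mean_first_event_time(self, fast_params):
        """From the all-healthy state every node ticks at gamma0, so the first
        event is the minimum of n exponential clocks: mean 1/(n gamma0)."""
        net = ag.HealthNetwork.from_edges(20, [(i, (i + 1) % 20) for i in range(20)],
                                          mortality_nodes=(0, 10))
        first = [
            simulate_lifetime(net, fast_params, seed=s).trajectory[0][0]
            for s in range(2000)
        ]
        expected = 1.0 / (20 * fast_params.gamma0)
        assert np.mean(first) == pytest.approx(expected, rel=0.08)

    def test_event_cap_raises(self, pair_network, fast_params):
        with pytest.raises(ag.dynamics.EventCapExceeded):
            # R tiny -> recovery dominates; death takes many events
            slow = ag.RateParameters(r_plus=0.01, r_minus=0.01, gamma0=1.0, R=0.001)
            simulate_lifetime(pair_network, slow, seed=0, max_events=50)


class TestSimulateCohort:
    def test_bit_identical_for_fixed_master_seed(self, small_network, fast_params):
        a = simulate_cohort(small_network, fast_params, 20, seed=9)
        b = simulate_cohort(small_network, fast_params, 20, seed=9)
        assert [r.tau for r in a] == [r.tau for r in b]

    def test_singleton_cohort_equals_single_lifetime(self, small_network, fast_params):
        from agingnet.dynamics import cohort_seeds

        cohort = simulate_cohort(small_network, fast_params, 1, seed=11, record=True)
        single = simulate_lifetime(
            small_network, fast_params, int(cohort_seeds(11, 1)[0])
        )
        assert cohort[0].tau == single.tau

    def test_jensen_gap_on_trajectories(self, generated_network, ref_params):
        """Empirical mean of e^{r+ p_hat(t)} dominates e^{r+ mean p_hat(t)}
        at every checkpoint (convexity of the damage-rate response)."""
        recs = simulate_cohort(generated_network, ref_params, 80, seed=4, record=True)
        checkpoints = np.arange(20.0, 80.0, 10.0)
        for t in checkpoints:
            phat_t = np.array(
                [
                    r.trajectory[1][np.searchsorted(r.trajectory[0], t) - 1]
                    if r.trajectory[0][0] <= t
                    else 0.0
                    for r in recs
                    if r.tau > t
                ]
            )
            if phat_t.size < 10:
                continue
            rp = ref_params.r_plus
            assert np.mean(np.exp(rp * phat_t)) >= np.exp(rp * phat_t.mean()) - 1e-12

    def test_cohort_mean_damage_increases_with_age(self, generated_network, ref_params):
        """With r+ >= r- and R >= 1 the population damage fraction drifts
        upward; checked on the cohort mean over a coarse age grid."""
        recs = simulate_cohort(generated_network, ref_params, 50, seed=8, record=True)
        grid = np.arange(10.0, 70.0, 10.0)
        means = []
        for t in grid:
            vals = [
                r.trajectory[1][np.searchsorted(r.trajectory[0], t) - 1]
                for r in recs
                if r.tau > t and r.trajectory[0][0] <= t
            ]
            means.append(np.mean(vals))
        assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))

    def test_damage_at_death_near_two_thirds(self, generated_network, ref_params):
        """Roughly two thirds of the nodes are damaged at death; the network
        value sits somewhat above the mean-field quadrature (whose rate
        approximation undershoots by Jensen's inequality)."""
        recs = simulate_cohort(generated_network, ref_params, 300, seed=2)
        mean_dd = np.mean([r.damage_at_death for r in recs])
        assert 0.55 <= mean_dd <= 0.85
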