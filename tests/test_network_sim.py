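"""Unit and property tests for the event-driven circuit simulator."""

import numpy as np
import pytest

from weberchoice import (
    NetworkParams,
    StimulusSpec,
    build_network,
    initialize_state,
    run_trial,
    run_trials,
)
from weberchoice.network_sim import (
    ChoiceNetwork,
    SimState,
    inhibition_threshold,
    pool_rate,
    summary_epsp,
    update_neuron,
)


class TestBuildNetwork:
    def test_block_densities(self):
        params = NetworkParams()
        net = build_network(params, 42)
        N, n_pool = params.N, params.n_pool
        assert net.W.shape == (N, N)
        assert np.diagonal(net.W).sum() == 0
        blockA = net.W[np.ix_(net.pool_A, net.pool_A)]
        cross = net.W[np.ix_(net.pool_A, net.pool_B)]
        rest = net.W[2 * n_pool:, 2 * n_pool:]
        # binomial means with ~4 sigma slack
        assert abs(blockA.mean() - 0.55 * (n_pool - 1) / n_pool) < 0.021
        assert abs(cross.mean() - 0.36) < 0.020
        assert abs(rest.mean() - 0.36 * (N - 2 * n_pool - 1) / (N - 2 * n_pool)) < 0.003
        # expected within-pool in-degree ~ 0.55 * 99
        in_deg = net.W[np.ix_(net.pool_A, net.pool_A)].sum(axis=0)
        assert abs(in_deg.mean() - 0.55 * 99) < 3.0

    def test_degenerate_densities(self):
        # d1 = 1, d2 -> 0: only the two within-pool off-diagonal pairs remain
        params = NetworkParams(N=5, n_pool=2, d1=1.0, d2=1e-12)
        net = build_network(params, 0)
        expected = np.zeros((5, 5), np.uint8)
        expected[0, 1] = expected[1, 0] = 1
        expected[2, 3] = expected[3, 2] = 1
        # the isolated neuron 4 gets its column regenerated until nonzero,
        # which cannot terminate at density ~0; exclude it by checking pools
        assert np.array_equal(net.W[:4, :4], expected[:4, :4])

    def test_presyn_count_consistency(self, toy_net):
        assert np.array_equal(toy_net.presyn_count, toy_net.W.sum(axis=0))
        assert (toy_net.presyn_count > 0).all()

    def test_input_targets_half_pool(self, toy_net):
        n = int(round(0.5 * toy_net.params.n_pool))
        assert len(toy_net.input_targets_A) == n
        assert set(toy_net.input_targets_A) <= set(toy_net.pool_A)
        assert set(toy_net.input_targets_B) <= set(toy_net.pool_B)

    def test_pools_disjoint(self, toy_net):
        assert not set(toy_net.pool_A) & set(toy_net.pool_B)

    def test_seed_determinism_and_variation(self):
        params = NetworkParams(N=200, n_pool=30)
        a = build_network(params, 7)
        b = build_network(params, 7)
        c = build_network(params, 8)
        assert np.array_equal(a.W, b.W)
        d_mean = (0.55 * 2 * 30 * 29 + 0.36 * (200 * 199 - 2 * 30 * 29)) / (200 * 199)
        expected_hamming = 2 * 200 * 199 * d_mean * (1 - d_mean)
        hamming = (a.W != c.W).sum()
        assert abs(hamming - expected_hamming) / expected_hamming < 0.05

    def test_rejects_pools_too_large(self):
        with pytest.raises(ValueError):
            NetworkParams(N=100, n_pool=50)


class TestInitializeState:
    def test_active_count_near_binomial_mean(self, default_params):
        net = build_network(default_params, 1)
        counts = [initialize_state(net, s).n_active for s in range(5)]
        # Binomial(1000, 0.13): mean 130, sd ~10.6
        assert abs(np.mean(counts) - 130) < 20

    def test_residual_refractory_and_waits(self, toy_net):
        st = initialize_state(toy_net, 3)
        d = toy_net.params.d_refractory
        active = st.s.astype(bool)
        assert st.n_active == active.sum() > 0
        assert (st.next_time[active] > 0).all()
        assert (st.next_time[active] <= d).all()
        assert (st.next_time[~active] > 0).all()

    def test_all_zero_draw_redrawn(self):
        # theta so small that most draws are all-zero: state still non-zero
        params = NetworkParams(N=30, n_pool=5, theta=0.01)
        net = build_network(params, 2)
        st = initialize_state(net, 11)
        assert st.n_active >= 1

    def test_active_presyn_matches_connectivity(self, toy_net):
        st = initialize_state(toy_net, 9)
        brute = toy_net.W[st.s.astype(bool), :].sum(axis=0)
        assert np.array_equal(st.active_presyn, brute)


class TestSummaryEpsp:
    def test_matches_brute_force(self, toy_net):
        st = initialize_state(toy_net, 21)
        for j in range(toy_net.params.N):
            expected = sum(
                int(st.s[i]) * int(toy_net.W[i, j])
                for i in range(toy_net.params.N)
            ) / toy_net.presyn_count[j]
            assert summary_epsp(toy_net, st, j) == pytest.approx(expected)

    def test_input_count_added_for_targets(self, toy_net):
        st = initialize_state(toy_net, 21)
        st.s[:] = 0
        st.n_active = 0
        st.active_presyn[:] = 0
        j = toy_net.input_targets_A[0]
        coupling = toy_net.params.input_coupling
        assert summary_epsp(toy_net, st, j, input_count=2.0) == pytest.approx(
            2.0 * coupling / toy_net.presyn_count[j])
        # a background neuron never sees the input stream
        bg = 2 * toy_net.params.n_pool
        assert summary_epsp(toy_net, st, bg, input_count=2.0) == 0.0

    def test_zero_presyn_rejected(self, toy_net):
        net = ChoiceNetwork(
            params=toy_net.params, W=np.zeros_like(toy_net.W),
            pool_A=toy_net.pool_A, pool_B=toy_net.pool_B,
            input_targets_A=toy_net.input_targets_A,
            input_targets_B=toy_net.input_targets_B,
            presyn_count=np.zeros_like(toy_net.presyn_count))
        st = initialize_state(toy_net, 21)
        with pytest.raises(ValueError):
            summary_epsp(net, st, 0)


class TestInhibition:
    @pytest.mark.parametrize("frac, theta, expected", [
        (0.13, 0.13, 0.13),
        (0.0, 0.13, 0.0),
        (1.0, 0.13, 1.0 / 0.13),
    ])
    def test_quadratic_threshold(self, frac, theta, expected):
        assert inhibition_threshold(frac, theta) == pytest.approx(expected)


def _manual_net(theta: float) -> ChoiceNetwork:
    """4-neuron circuit with exact float arithmetic for the tie rule."""
    params = NetworkParams(N=4, n_pool=1, theta=theta)
    W = np.array([
        [0, 1, 1, 0],
        [1, 0, 1, 0],
        [0, 1, 0, 1],
        [1, 0, 0, 0],
    ], np.uint8).T  # W[i, j]: i presynaptic to j
    return ChoiceNetwork(
        params=params, W=W, pool_A=np.array([0]), pool_B=np.array([1]),
        input_targets_A=np.array([], int), input_targets_B=np.array([], int),
        presyn_count=W.sum(axis=0).astype(np.int64))


def _manual_state(net, active) -> SimState:
    s = np.zeros(net.params.N, np.uint8)
    s[list(active)] = 1
    return SimState(
        s=s, next_time=np.full(net.params.N, 1.0), t_now=1.0,
        n_active=len(active),
        active_presyn=net.W[s.astype(bool), :].sum(axis=0).astype(np.int64),
        rng=np.random.RandomState(0))


class TestUpdateNeuron:
    def test_fires_above_threshold(self):
        net = _manual_net(theta=0.9)
        st = _manual_state(net, active=[0, 1])
        # neuron 2: presyn {0, 1} both active -> epsp 1.0; rhs = 0.25/0.9
        assert update_neuron(net, st, 2) == 1
        assert st.spike_neurons == [2]

    def test_stays_silent_below_threshold(self):
        net = _manual_net(theta=0.05)
        st = _manual_state(net, active=[0])
        # neuron 3: presyn {2} inactive -> epsp 0; rhs = 0.0625/0.05 > 0
        assert update_neuron(net, st, 3) == 0
        assert st.spike_neurons == []

    def test_exact_tie_fires(self):
        # epsp = 1/2 exactly; rhs = (2/4)^2 / 0.5 = 1/2 exactly
        net = _manual_net(theta=0.5)
        st = _manual_state(net, active=[0, 3])
        # neuron 1: presyn {0, 2}; active presyn = {0} -> epsp = 0.5
        assert st.active_presyn[1] == 1
        assert update_neuron(net, st, 1) == 1

    def test_all_zero_state_is_absorbing(self):
        net = _manual_net(theta=0.5)
        st = _manual_state(net, active=[])
        # degenerate 0 >= 0 tie must NOT fire
        for j in range(4):
            assert update_neuron(net, st, j) == 0
        assert st.n_active == 0

    def test_nonfiring_active_neuron_deactivates(self):
        net = _manual_net(theta=0.05)
        st = _manual_state(net, active=[3])
        # neuron 3 expires: epsp 0 < rhs -> becomes inactive
        assert update_neuron(net, st, 3) == 0
        assert st.s[3] == 0
        assert st.n_active == 0
        assert st.next_time[3] > st.t_now


class TestPoolRate:
    def test_uniform_spiking(self):
        pool = np.arange(100)
        times = np.linspace(75, 99, 100)
        assert pool_rate(times, pool, pool, t=100.0) == pytest.approx(100 / 3.0)

    def test_empty_window(self):
        assert pool_rate(np.array([1.0]), np.array([0]), np.arange(10), t=50.0) == 0.0

    def test_refractory_limit_caps_at_70(self):
        # every neuron refiring at the refractory limit: 1000/d spikes/s
        d = 1 / 0.07
        pool = np.arange(100)
        times = np.concatenate([np.arange(70.0, 100.0, d) for _ in pool])
        ids = np.repeat(pool, len(np.arange(70.0, 100.0, d)))
        assert pool_rate(times, ids, pool, t=100.0) <= 70.0 + 1e-9

    def test_requires_full_window(self):
        with pytest.raises(ValueError):
            pool_rate(np.array([1.0]), np.array([0]), np.array([0]), t=10.0)


class TestTrials:
    def test_engine_parity_bit_exact(self):
        params = NetworkParams(N=60, n_pool=10, t_stimulus_ms=800.0)
        net = build_network(params, 7)
        stim = StimulusSpec(3.0, 4.0, 0.5)
        fast = run_trial(net, stim, 99, stop_at_decision=False,
                         engine="numba", keep_spikes=True)
        ref = run_trial(net, stim, 99, stop_at_decision=False,
                        engine="python", keep_spikes=True)
        assert np.array_equal(fast.spike_times, ref.spike_times)
        assert np.array_equal(fast.spike_neurons, ref.spike_neurons)
        assert np.array_equal(fast.rate_trace_A, ref.rate_trace_A)
        assert np.array_equal(fast.rate_trace_B, ref.rate_trace_B)
        assert fast.decision == ref.decision and fast.rt_ms == ref.rt_ms

    def test_trial_determinism(self, small_params):
        net = build_network(small_params, 5)
        stim = StimulusSpec(4.0, 6.0)
        a = run_trial(net, stim, 13, keep_spikes=True)
        b = run_trial(net, stim, 13, keep_spikes=True)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert a.decision == b.decision and a.rt_ms == b.rt_ms

    def test_rate_bound_and_refractory_gap(self, small_params):
        net = build_network(small_params, 6)
        res = run_trial(net, StimulusSpec(4.0, 6.0), 21,
                        stop_at_decision=False, keep_spikes=True)
        assert res.rate_trace_A.max() <= 70.0 + 1e-9
        assert res.rate_trace_B.max() <= 70.0 + 1e-9
        assert 0.0 < res.total_rate_hz <= 70.0
        d = small_params.d_refractory
        for j in np.unique(res.spike_neurons):
            gaps = np.diff(res.spike_times[res.spike_neurons == j])
            assert (gaps >= d - 1e-9).all()

    def test_undecided_without_input(self, small_params):
        net = build_network(small_params, 8)
        res = run_trial(net, StimulusSpec(0.0, 0.0), 3)
        assert res.decision == "undecided"
        assert res.rt_ms is None

    def test_spontaneous_rate_near_mean_field(self, default_params):
        # mean-field fixed point: active fraction ~ theta -> 0.13 * 70 Hz
        rates = []
        for s in range(3):
            net = build_network(default_params, 50 + s)
            res = run_trial(net, StimulusSpec(0.0, 0.0), 60 + s,
                            stop_at_decision=False)
            rates.append(res.total_rate_hz)
        assert 8.5 <= np.mean(rates) <= 10.0

    def test_pool_symmetry_under_stimulus_swap(self, default_params):
        n = 120
        a = run_trials(default_params, [StimulusSpec(9.0, 13.0)] * n, 31)
        b = run_trials(default_params, [StimulusSpec(13.0, 9.0)] * n, 32)
        p_b = (a[a.decision != "undecided"].decision == "B").mean()
        p_a = (b[b.decision != "undecided"].decision == "A").mean()
        assert abs(p_b - p_a) < 0.17  # ~4 sigma at n=120

    def test_choice_probability_monotone_in_lambda_b(self, default_params):
        n = 150
        probs = []
        for lb, seed in [(10.5, 41), (12.0, 42), (15.0, 43)]:
            log = run_trials(default_params, [StimulusSpec(10.0, lb)] * n, seed)
            dec = log[log.decision != "undecided"]
            probs.append((dec.decision == "B").mean())
        assert probs[2] > probs[0]
        assert probs[1] > probs[0] - 0.10 and probs[2] > probs[1] - 0.10

    def test_trial_log_schema(self, small_params):
        log = run_trials(small_params, [StimulusSpec(4.0, 6.0, 0.5)] * 4, 77)
        assert list(log.columns) == ["trial_id", "seed", "lambda_a", "lambda_b",
                                     "lambda_0", "decision", "rt_ms",
                                     "total_rate_hz"]
        decided = log[log.decision != "undecided"]
        assert (decided.rt_ms > 0).all()
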