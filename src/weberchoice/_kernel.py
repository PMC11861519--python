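"""Numba event loop for the binary-neuron choice circuit.

The kernel mirrors, step for step and RNG draw for RNG draw, the pure-Python
reference engine in :mod:`weberchoice.network_sim` (numba's legacy ``np.random``
is bit-compatible with ``numpy.random.RandomState``).  Any change to the event
semantics must be made in both places; the cross-engine test enforces this.
"""

import numpy as np
from numba import njit

# decision codes
UNDECIDED = 0
DECISION_A = 1
DECISION_B = 2


# Indexed binary min-heap over per-neuron event times.  Ties are broken by
# neuron index (matching np.argmin in the reference engine).  Every neuron
# always has exactly one pending event, so the heap size is fixed at N and
# rescheduling is a key update followed by a sift.

@njit(cache=True, inline="always")
def _heap_less(keys, ids, a, b):
    return keys[a] < keys[b] or (keys[a] == keys[b] and ids[a] < ids[b])


@njit(cache=True)
def _sift_down(keys, ids, pos, i):
    n = keys.shape[0]
    while True:
        left = 2 * i + 1
        if left >= n:
            return
        child = left
        right = left + 1
        if right < n and _heap_less(keys, ids, right, left):
            child = right
        if _heap_less(keys, ids, child, i):
            keys[i], keys[child] = keys[child], keys[i]
            ids[i], ids[child] = ids[child], ids[i]
            pos[ids[i]] = i
            pos[ids[child]] = child
            i = child
        else:
            return


@njit(cache=True)
def _sift_up(keys, ids, pos, i):
    while i > 0:
        parent = (i - 1) // 2
        if _heap_less(keys, ids, i, parent):
            keys[i], keys[parent] = keys[parent], keys[i]
            ids[i], ids[parent] = ids[parent], ids[i]
            pos[ids[i]] = i
            pos[ids[parent]] = parent
            i = parent
        else:
            return


@njit(cache=True)
def _heap_update(keys, ids, pos, neuron, new_key):
    i = pos[neuron]
    keys[i] = new_key
    _sift_up(keys, ids, pos, i)
    _sift_down(keys, ids, pos, i)


@njit(cache=True)
def run_kernel(
    out_ptr,          # int64[N+1]  CSR offsets: postsynaptic targets of neuron i
    out_idx,          # int32[nnz]  CSR column indices
    presyn_count,     # int64[N]    number of presynaptic connections of each neuron
    input_flag,       # int8[N]     0 = none, 1 = pool-A input target, 2 = pool-B
    pool_flag,        # int8[N]     0 = background, 1 = pool A, 2 = pool B
    n_pool,
    theta,
    d_refractory,
    update_rate,
    coupling,
    lambda_a,
    lambda_b,
    lambda_0,
    t_spontaneous,
    t_stimulus,
    input_bin_ms,
    rate_window_ms,
    rate_step_ms,
    threshold_hz,
    stop_at_decision,  # boolean
    seed,
):
    np.random.seed(seed)
    N = presyn_count.shape[0]
    t_end = t_spontaneous + t_stimulus

    # --- initial state: active with probability theta, redraw if all zero ---
    s = np.zeros(N, np.uint8)
    n_active = 0
    while n_active == 0:
        n_active = 0
        for i in range(N):
            if np.random.random() < theta:
                s[i] = 1
                n_active += 1
            else:
                s[i] = 0

    next_time = np.empty(N, np.float64)
    for i in range(N):
        if s[i] == 1:
            # residual refractory time on (0, d]
            next_time[i] = d_refractory * (1.0 - np.random.random())
        else:
            next_time[i] = np.random.exponential(1.0 / update_rate)

    # event queue
    heap_keys = next_time.copy()
    heap_ids = np.arange(N, dtype=np.int64)
    heap_pos = np.arange(N, dtype=np.int64)
    for i in range(N // 2 - 1, -1, -1):
        _sift_down(heap_keys, heap_ids, heap_pos, i)

    # per-neuron count of currently active presynaptic neurons
    active_presyn = np.zeros(N, np.int64)
    for i in range(N):
        if s[i] == 1:
            for k in range(out_ptr[i], out_ptr[i + 1]):
                active_presyn[out_idx[k]] += 1

    # --- spike log ---
    cap = N * (int(t_end / d_refractory) + 2)
    spike_t = np.empty(cap, np.float64)
    spike_id = np.empty(cap, np.int32)
    n_spikes = 0
    # pool spike times for the sliding-window rate estimator
    cap_pool = n_pool * (int(t_end / d_refractory) + 2)
    a_times = np.empty(cap_pool, np.float64)
    b_times = np.empty(cap_pool, np.float64)
    n_a = 0
    n_b = 0
    tail_a = 0
    tail_b = 0

    # --- rate-sample grid ---
    n_samp_max = int((t_end - rate_window_ms) / rate_step_ms) + 2
    trace_t = np.empty(n_samp_max, np.float64)
    trace_a = np.empty(n_samp_max, np.float64)
    trace_b = np.empty(n_samp_max, np.float64)
    n_samp = 0
    next_samp = rate_window_ms

    # --- stimulus bins ---
    next_bin = t_spontaneous
    x_a = 0.0
    x_b = 0.0

    decision = UNDECIDED
    decision_time = np.nan
    rate_norm = n_pool * rate_window_ms / 1000.0  # spikes -> Hz
    stopped = False

    while True:
        # next neuron event
        j = heap_ids[0]
        t = heap_keys[0]
        t_cap = t if t < t_end else t_end

        # flush scheduled grid points (rate samples, stimulus bins) up to t_cap;
        # at equal times the rate sample is processed first (it does not draw RNG)
        while True:
            if next_samp <= t_cap and next_samp <= next_bin:
                tau = next_samp
                lo = tau - rate_window_ms
                while tail_a < n_a and a_times[tail_a] <= lo:
                    tail_a += 1
                while tail_b < n_b and b_times[tail_b] <= lo:
                    tail_b += 1
                ra = (n_a - tail_a) / rate_norm
                rb = (n_b - tail_b) / rate_norm
                trace_t[n_samp] = tau
                trace_a[n_samp] = ra
                trace_b[n_samp] = rb
                n_samp += 1
                if decision == UNDECIDED and tau > t_spontaneous and (
                    ra >= threshold_hz or rb >= threshold_hz
                ):
                    # tie (both pools cross in the same sample): higher rate wins,
                    # exact tie resolved in favour of A
                    decision = DECISION_A if ra >= rb else DECISION_B
                    decision_time = tau
                    if stop_at_decision:
                        stopped = True
                        break
                next_samp += rate_step_ms
            elif next_bin <= t_cap and next_bin < t_end:
                x_a = float(np.random.poisson(lambda_a)) if lambda_a > 0.0 else 0.0
                x_b = float(np.random.poisson(lambda_b)) if lambda_b > 0.0 else 0.0
                if lambda_0 > 0.0:
                    x_a += float(np.random.poisson(lambda_0))
                    x_b += float(np.random.poisson(lambda_0))
                next_bin += input_bin_ms
            else:
                break
        if stopped or t >= t_end:
            break

        # --- neuron update ---
        inp = 0.0
        if input_flag[j] == 1:
            inp = x_a
        elif input_flag[j] == 2:
            inp = x_b
        num = active_presyn[j] + coupling * inp
        frac = n_active / N
        rhs = frac * frac / theta
        # ties fire, except the degenerate 0 >= 0 case (preserves the silent
        # absorbing state)
        fire = num / presyn_count[j] >= rhs and not (num == 0.0 and rhs == 0.0)

        if s[j] == 1:
            if fire:  # immediate refire at refractory expiry
                spike_t[n_spikes] = t
                spike_id[n_spikes] = j
                n_spikes += 1
                if pool_flag[j] == 1:
                    a_times[n_a] = t
                    n_a += 1
                elif pool_flag[j] == 2:
                    b_times[n_b] = t
                    n_b += 1
                _heap_update(heap_keys, heap_ids, heap_pos, j, t + d_refractory)
            else:
                s[j] = 0
                n_active -= 1
                for k in range(out_ptr[j], out_ptr[j + 1]):
                    active_presyn[out_idx[k]] -= 1
                _heap_update(heap_keys, heap_ids, heap_pos, j,
                             t + np.random.exponential(1.0 / update_rate))
        else:
            if fire:
                s[j] = 1
                n_active += 1
                for k in range(out_ptr[j], out_ptr[j + 1]):
                    active_presyn[out_idx[k]] += 1
                spike_t[n_spikes] = t
                spike_id[n_spikes] = j
                n_spikes += 1
                if pool_flag[j] == 1:
                    a_times[n_a] = t
                    n_a += 1
                elif pool_flag[j] == 2:
                    b_times[n_b] = t
                    n_b += 1
                _heap_update(heap_keys, heap_ids, heap_pos, j, t + d_refractory)
            else:
                _heap_update(heap_keys, heap_ids, heap_pos, j,
                             t + np.random.exponential(1.0 / update_rate))

    elapsed = decision_time if stopped else t_end
    return (
        spike_t[:n_spikes].copy(),
        spike_id[:n_spikes].copy(),
        decision,
        decision_time,
        trace_t[:n_samp].copy(),
        trace_a[:n_samp].copy(),
        trace_b[:n_samp].copy(),
        elapsed,
    )
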