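"""Event-driven recurrent attractor network of binary neurons with global inhibition.

The circuit is a pool of ``N`` excitatory binary neurons.  A neuron is in state
1 while inside its effective refractory period (length ``d``, which also acts
as the integration window and caps single-neuron rates at ``1000/d`` Hz) and 0
otherwise.  Inhibitory neurons are not modelled explicitly: a global inhibition
term, quadratic in the mean network activity and scaled by ``1/Θ``, enters the
update rule directly.  A neuron being updated switches to 1 (and emits a spike)
iff its normalized summary EPSP reaches that global threshold:

    (Σ_i s(i)·w_ij + input) / Σ_i w_ij  >=  (Σ_i s(i)/N)² / Θ

Updates are asynchronous: inactive neurons are revisited by a Poisson process
(rate ``update_rate`` per ms), active neurons at their refractory expiry.  Two
decision pools A and B (denser internal connectivity ``d1`` vs ``d2``
elsewhere) receive Poisson spike-count inputs with means ``λ_A``, ``λ_B`` per
30 ms bin; a decision is read out when either pool's windowed firing rate
crosses the decision threshold.

Two engines implement identical event semantics: a fast numba kernel
(default) and a pure-Python reference used for exact unit testing; with the
same seed they produce bit-identical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernel

__all__ = [
    "NetworkParams",
    "StimulusSpec",
    "ChoiceNetwork",
    "SimState",
    "TrialResult",
    "build_network",
    "initialize_state",
    "summary_epsp",
    "inhibition_threshold",
    "update_neuron",
    "pool_rate",
    "run_trial",
    "run_trials",
    "post_decision_rates",
]

MAX_RATE_HZ = 70.0


@dataclass(frozen=True)
class NetworkParams:
    """Control parameters of the choice circuit.

    Defaults are the standard operating point: the network is multi-stable
    (spontaneous state plus two decision attractors) and fires spontaneously
    at ~9.2 Hz.
    """

    N: int = 1000
    n_pool: int = 100
    theta: float = 0.13
    d_refractory: float = 1.0 / 0.07     # ms; sets the 70 Hz rate ceiling
    update_rate: float = 0.006           # per ms per inactive neuron
    d1: float = 0.55                     # within-decision-pool density
    d2: float = 0.36                     # all other ordered pairs
    decision_threshold_hz: float = 50.0
    rate_window_ms: float = 30.0
    rate_step_ms: float = 10.0
    input_bin_ms: float = 30.0
    input_fraction: float = 0.5
    input_coupling: float = 0.8          # EPSP weight of one input spike (calibrated against the psychometric curve)
    t_spontaneous_ms: float = 500.0
    t_stimulus_ms: float = 5000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if not (0.0 < self.d1 <= 1.0 and 0.0 < self.d2 <= 1.0):
            raise ValueError("densities d1, d2 must lie in (0, 1]")
        if 2 * self.n_pool >= self.N:
            raise ValueError("need 2*n_pool < N")
        for name in ("d_refractory", "rate_window_ms", "rate_step_ms",
                     "input_bin_ms", "t_stimulus_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_spontaneous_ms < 0:
            raise ValueError("t_spontaneous_ms must be nonnegative")
        if not 0.0 < self.input_fraction <= 1.0:
            raise ValueError("input_fraction must lie in (0, 1]")

    @property
    def max_rate_hz(self) -> float:
        return 1000.0 / self.d_refractory

    def with_(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusSpec:
    """Poisson input means per 30 ms bin (dimensionless evidence units).

    ``lambda_0`` is independent background noise added to both pools' input
    targets; the default 1.875 used in the noise analysis corresponds to 25
    input neurons spiking at 2.5 Hz over a 30 ms bin.
    """

    lambda_A: float
    lambda_B: float
    lambda_0: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_A < 0 or self.lambda_B < 0 or self.lambda_0 < 0:
            raise ValueError("stimulus rates must be nonnegative")


@dataclass
class ChoiceNetwork:
    """A realized circuit: connectivity, pool membership, input targets."""

    params: NetworkParams
    W: np.ndarray                 # uint8 (N, N); W[i, j] = 1: i presynaptic to j
    pool_A: np.ndarray            # int indices, size n_pool
    pool_B: np.ndarray
    input_targets_A: np.ndarray   # subset of pool_A
    input_targets_B: np.ndarray
    presyn_count: np.ndarray      # column sums of W
    # CSR adjacency (targets of each presynaptic neuron), built lazily
    _out_ptr: np.ndarray | None = field(default=None, repr=False)
    _out_idx: np.ndarray | None = field(default=None, repr=False)

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        if self._out_ptr is None:
            src, dst = np.nonzero(self.W)
            self._out_idx = dst.astype(np.int32)
            self._out_ptr = np.zeros(self.params.N + 1, np.int64)
            np.cumsum(np.bincount(src, minlength=self.params.N),
                      out=self._out_ptr[1:])
        return self._out_ptr, self._out_idx

    def input_flag(self) -> np.ndarray:
        flag = np.zeros(self.params.N, np.int8)
        flag[self.input_targets_A] = 1
        flag[self.input_targets_B] = 2
        return flag

    def pool_flag(self) -> np.ndarray:
        flag = np.zeros(self.params.N, np.int8)
        flag[self.pool_A] = 1
        flag[self.pool_B] = 2
        return flag


@dataclass
class SimState:
    """Mutable simulation state for the reference engine."""

    s: np.ndarray                 # uint8 (N,)
    next_time: np.ndarray         # ms; refractory expiry if active, else Poisson update
    t_now: float
    n_active: int
    active_presyn: np.ndarray     # per-neuron count of active presynaptic neurons
    rng: np.random.RandomState
    spike_times: list = field(default_factory=list)
    spike_neurons: list = field(default_factory=list)
    current_input_A: float = 0.0
    current_input_B: float = 0.0


@dataclass
class TrialResult:
    """One simulation run of the circuit."""

    decision: str                 # "A", "B" or "undecided"
    rt_ms: float | None           # stimulus onset -> first threshold crossing
    trace_t_ms: np.ndarray
    rate_trace_A: np.ndarray      # Hz, windowed pool rates per rate_step_ms
    rate_trace_B: np.ndarray
    total_rate_hz: float          # population-average rate over the whole run
    n_spikes: int
    seed: int
    spike_times: np.ndarray | None = None
    spike_neurons: np.ndarray | None = None


# ---------------------------------------------------------------------------
# network construction


def build_network(params: NetworkParams, rng_seed: int) -> ChoiceNetwork:
    """Draw a random binary connectivity and pool/input membership.

    Ordered pairs inside the same decision pool connect with probability
    ``d1``, every other ordered pair with ``d2``; no self-connections and no
    symmetry constraint.  A fresh network is normally drawn before every
    trial.  Any neuron left with zero presynaptic connections has its inputs
    redrawn (practically relevant only for toy-sized networks).
    """
    rng = np.random.default_rng(rng_seed)
    N, n_pool = params.N, params.n_pool
    pool_A = np.arange(0, n_pool)
    pool_B = np.arange(n_pool, 2 * n_pool)

    W = (rng.random((N, N)) < params.d2).astype(np.uint8)
    blockA = np.ix_(pool_A, pool_A)
    blockB = np.ix_(pool_B, pool_B)
    W[blockA] = rng.random((n_pool, n_pool)) < params.d1
    W[blockB] = rng.random((n_pool, n_pool)) < params.d1
    np.fill_diagonal(W, 0)

    # regenerate all-zero presynaptic columns (practically only possible in
    # toy-sized or near-zero-density networks); bounded so degenerate
    # densities cannot spin forever
    presyn = W.sum(axis=0).astype(np.int64)
    for _ in range(50):
        if not (presyn == 0).any():
            break
        for j in np.flatnonzero(presyn == 0):
            col = (rng.random(N) < params.d2).astype(np.uint8)
            if j < 2 * n_pool:
                pool = pool_A if j < n_pool else pool_B
                col[pool] = rng.random(n_pool) < params.d1
            col[j] = 0
            W[:, j] = col
        presyn = W.sum(axis=0).astype(np.int64)

    n_in = int(round(params.input_fraction * n_pool))
    targets_A = np.sort(rng.choice(pool_A, size=n_in, replace=False))
    targets_B = np.sort(rng.choice(pool_B, size=n_in, replace=False))
    return ChoiceNetwork(params, W, pool_A, pool_B, targets_A, targets_B, presyn)


def initialize_state(net: ChoiceNetwork, rng_seed: int) -> SimState:
    """Random non-zero initial state: each neuron active with probability Θ.

    Active neurons receive a residual refractory time uniform on ``(0, d]``
    (avoids a synchronized expiry at ``t = d``); inactive neurons get an
    exponential waiting time for their first Poisson update.  An all-zero
    draw is rejected and redrawn.
    """
    p = net.params
    rng = np.random.RandomState(rng_seed)
    s = np.zeros(p.N, np.uint8)
    n_active = 0
    while n_active == 0:
        n_active = 0
        for i in range(p.N):
            if rng.random_sample() < p.theta:
                s[i] = 1
                n_active += 1
            else:
                s[i] = 0
    next_time = np.empty(p.N)
    for i in range(p.N):
        if s[i]:
            next_time[i] = p.d_refractory * (1.0 - rng.random_sample())
        else:
            next_time[i] = rng.exponential(1.0 / p.update_rate)
    active_presyn = (net.W[s.astype(bool), :]).sum(axis=0).astype(np.int64)
    return SimState(s=s, next_time=next_time, t_now=0.0, n_active=n_active,
                    active_presyn=active_presyn, rng=rng)


# ---------------------------------------------------------------------------
# single-neuron operations (reference semantics)


def summary_epsp(net: ChoiceNetwork, state: SimState, j: int,
                 input_count: float = 0.0) -> float:
    """Normalized summary EPSP of neuron ``j``.

    Sum of presynaptic states (plus the current input count if ``j`` is an
    input target, weighted by the coupling constant), normalized by the
    number of presynaptic connections.
    """
    if net.presyn_count[j] == 0:
        raise ValueError(f"neuron {j} has no presynaptic connections")
    inp = 0.0
    if j in net.input_targets_A or j in net.input_targets_B:
        inp = net.params.input_coupling * input_count
    num = float(state.s @ net.W[:, j]) + inp
    return num / net.presyn_count[j]


def inhibition_threshold(state: SimState | float, theta: float) -> float:
    """Global inhibition level: (active fraction)² / Θ."""
    if isinstance(state, SimState):
        frac = state.n_active / state.s.shape[0]
    else:
        frac = float(state)
    return frac * frac / theta


def update_neuron(net: ChoiceNetwork, state: SimState, j: int) -> int:
    """Apply the update rule to neuron ``j`` at ``state.t_now``; mutate state.

    Fires (state 1, spike logged) iff EPSP >= inhibition, ties firing except
    the degenerate 0 >= 0 case with no presynaptic input — an all-zero,
    input-free network stays silent.  A non-firing neuron is handed back to
    the Poisson update process.
    """
    p = net.params
    inp = 0.0
    if net.input_flag()[j] == 1:
        inp = state.current_input_A
    elif net.input_flag()[j] == 2:
        inp = state.current_input_B
    num = float(state.active_presyn[j]) + p.input_coupling * inp
    rhs = inhibition_threshold(state.n_active / p.N, p.theta)
    fire = (num / net.presyn_count[j] >= rhs) and not (num == 0.0 and rhs == 0.0)
    t = state.t_now
    post = np.flatnonzero(net.W[j])
    if state.s[j] == 1:
        if fire:
            state.spike_times.append(t)
            state.spike_neurons.append(j)
            state.next_time[j] = t + p.d_refractory
            return 1
        state.s[j] = 0
        state.n_active -= 1
        state.active_presyn[post] -= 1
        state.next_time[j] = t + state.rng.exponential(1.0 / p.update_rate)
        return 0
    if fire:
        state.s[j] = 1
        state.n_active += 1
        state.active_presyn[post] += 1
        state.spike_times.append(t)
        state.spike_neurons.append(j)
        state.next_time[j] = t + p.d_refractory
        return 1
    state.next_time[j] = t + state.rng.exponential(1.0 / p.update_rate)
    return 0


def pool_rate(spike_times: np.ndarray, spike_neurons: np.ndarray,
              pool: np.ndarray, t: float, window_ms: float = 30.0,
              n_pool: int | None = None) -> float:
    """Windowed pool firing rate in Hz: spikes of pool members in (t-w, t]."""
    if t < window_ms:
        raise ValueError("t must be at least one window length")
    spike_times = np.asarray(spike_times)
    spike_neurons = np.asarray(spike_neurons)
    in_win = (spike_times > t - window_ms) & (spike_times <= t)
    count = np.isin(spike_neurons[in_win], pool).sum()
    n = len(pool) if n_pool is None else n_pool
    return count / (n * window_ms / 1000.0)


# ---------------------------------------------------------------------------
# trial engines

_DECISION_LABEL = {_kernel.UNDECIDED: "undecided",
                   _kernel.DECISION_A: "A",
                   _kernel.DECISION_B: "B"}


def run_trial(net: ChoiceNetwork, stim: StimulusSpec, rng_seed: int,
              stop_at_decision: bool = True, engine: str = "numba",
              keep_spikes: bool = False) -> TrialResult:
    """Simulate one trial: spontaneous run, stimulus, threshold readout.

    The stimulus is delivered after ``t_spontaneous_ms`` of spontaneous
    evolution and maintained for ``t_stimulus_ms``; per-pool input counts are
    redrawn each 30 ms bin.  The trial ends at the first threshold crossing
    by either pool after onset (``stop_at_decision``) or at the end of the
    stimulus period; reaching neither threshold is a valid "undecided"
    outcome.
    """
    p = net.params
    out_ptr, out_idx = net.adjacency()
    args = (
        out_ptr, out_idx, net.presyn_count, net.input_flag(), net.pool_flag(),
        p.n_pool, p.theta, p.d_refractory, p.update_rate, p.input_coupling,
        stim.lambda_A, stim.lambda_B, stim.lambda_0,
        p.t_spontaneous_ms, p.t_stimulus_ms, p.input_bin_ms,
        p.rate_window_ms, p.rate_step_ms, p.decision_threshold_hz,
        stop_at_decision, rng_seed,
    )
    if engine == "numba":
        (st, sid, decision, decision_time,
         tt, ta, tb, elapsed) = _kernel.run_kernel(*args)
    elif engine == "python":
        (st, sid, decision, decision_time,
         tt, ta, tb, elapsed) = _run_trial_python(net, stim, rng_seed,
                                                  stop_at_decision)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    rt = None
    if decision != _kernel.UNDECIDED:
        rt = float(decision_time) - p.t_spontaneous_ms
    total_rate = len(st) / (p.N * elapsed / 1000.0)
    return TrialResult(
        decision=_DECISION_LABEL[int(decision)], rt_ms=rt,
        trace_t_ms=np.asarray(tt), rate_trace_A=np.asarray(ta),
        rate_trace_B=np.asarray(tb), total_rate_hz=float(total_rate),
        n_spikes=len(st), seed=int(rng_seed),
        spike_times=np.asarray(st) if keep_spikes else None,
        spike_neurons=np.asarray(sid) if keep_spikes else None,
    )


def _run_trial_python(net: ChoiceNetwork, stim: StimulusSpec, rng_seed: int,
                      stop_at_decision: bool):
    """Reference engine; draw-for-draw identical to the numba kernel."""
    p = net.params
    state = initialize_state(net, rng_seed)
    rng = state.rng
    in_flag = net.input_flag()
    pool_flag = net.pool_flag()
    t_end = p.t_spontaneous_ms + p.t_stimulus_ms
    rate_norm = p.n_pool * p.rate_window_ms / 1000.0

    a_times: list[float] = []
    b_times: list[float] = []
    tail_a = tail_b = 0
    trace_t: list[float] = []
    trace_a: list[float] = []
    trace_b: list[float] = []
    next_samp = p.rate_window_ms
    next_bin = p.t_spontaneous_ms
    decision = _kernel.UNDECIDED
    decision_time = np.nan
    stopped = False

    while True:
        j = int(np.argmin(state.next_time))
        t = state.next_time[j]
        t_cap = min(t, t_end)
        while True:
            if next_samp <= t_cap and next_samp <= next_bin:
                tau = next_samp
                lo = tau - p.rate_window_ms
                while tail_a < len(a_times) and a_times[tail_a] <= lo:
                    tail_a += 1
                while tail_b < len(b_times) and b_times[tail_b] <= lo:
                    tail_b += 1
                ra = (len(a_times) - tail_a) / rate_norm
                rb = (len(b_times) - tail_b) / rate_norm
                trace_t.append(tau)
                trace_a.append(ra)
                trace_b.append(rb)
                if decision == _kernel.UNDECIDED and tau > p.t_spontaneous_ms \
                        and (ra >= p.decision_threshold_hz
                             or rb >= p.decision_threshold_hz):
                    decision = (_kernel.DECISION_A if ra >= rb
                                else _kernel.DECISION_B)
                    decision_time = tau
                    if stop_at_decision:
                        stopped = True
                        break
                next_samp += p.rate_step_ms
            elif next_bin <= t_cap and next_bin < t_end:
                state.current_input_A = (float(rng.poisson(stim.lambda_A))
                                         if stim.lambda_A > 0 else 0.0)
                state.current_input_B = (float(rng.poisson(stim.lambda_B))
                                         if stim.lambda_B > 0 else 0.0)
                if stim.lambda_0 > 0:
                    state.current_input_A += float(rng.poisson(stim.lambda_0))
                    state.current_input_B += float(rng.poisson(stim.lambda_0))
                next_bin += p.input_bin_ms
            else:
                break
        if stopped or t >= t_end:
            break
        state.t_now = t
        n_before = len(state.spike_times)
        update_neuron(net, state, j)
        if len(state.spike_times) > n_before:
            if pool_flag[j] == 1:
                a_times.append(t)
            elif pool_flag[j] == 2:
                b_times.append(t)

    elapsed = decision_time if stopped else t_end
    return (np.asarray(state.spike_times), np.asarray(state.spike_neurons,
            dtype=np.int32), decision, decision_time, np.asarray(trace_t),
            np.asarray(trace_a), np.asarray(trace_b), elapsed)


# ---------------------------------------------------------------------------
# batch runner


def run_trials(params: NetworkParams, stimuli: Sequence[StimulusSpec],
               rng_seed: int, fresh_network: bool = True,
               stop_at_decision: bool = True) -> pd.DataFrame:
    """Run one trial per stimulus and return a tidy trial log.

    By default a new connectivity is drawn before every trial; with
    ``fresh_network=False`` a single network (seeded from ``rng_seed``) is
    shared across the batch.
    """
    net_stream, trial_stream = np.random.SeedSequence(rng_seed).spawn(2)
    net_seeds = net_stream.generate_state(len(stimuli))
    trial_seeds = trial_stream.generate_state(len(stimuli))
    shared = None if fresh_network else build_network(params, int(net_seeds[0]))
    rows = []
    for k, stim in enumerate(stimuli):
        net = shared if shared is not None else build_network(
            params, int(net_seeds[k]))
        res = run_trial(net, stim, int(trial_seeds[k]),
                        stop_at_decision=stop_at_decision)
        rows.append({
            "trial_id": k,
            "seed": res.seed,
            "lambda_a": stim.lambda_A,
            "lambda_b": stim.lambda_B,
            "lambda_0": stim.lambda_0,
            "decision": res.decision,
            "rt_ms": res.rt_ms if res.rt_ms is not None else np.nan,
            "total_rate_hz": res.total_rate_hz,
        })
    return pd.DataFrame(rows)


def post_decision_rates(result: TrialResult, params: NetworkParams,
                        settle_ms: float = 200.0) -> tuple[float, float]:
    """Mean windowed rates (winner, loser) from ``settle_ms`` after the
    threshold crossing to the end of the run; requires a decided trial run
    to completion."""
    if result.decision == "undecided" or result.rt_ms is None:
        raise ValueError("trial is undecided")
    t_cross = params.t_spontaneous_ms + result.rt_ms
    sel = result.trace_t_ms >= t_cross + settle_ms
    if not sel.any():
        raise ValueError("no post-decision samples; was the trial truncated?")
    ra = result.rate_trace_A[sel].mean()
    rb = result.rate_trace_B[sel].mean()
    return (ra, rb) if result.decision == "A" else (rb, ra)
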