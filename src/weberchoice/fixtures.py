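"""Synthetic test inputs for the analysis layers.

Every generator is a pure function of its spec (including the seed), so the
statistics code is testable without running the circuit simulator: choice
data drawn from a known Weibull psychometric, RT samples drawn from a gamma
family, and a hand-checkable toy network for exact unit tests of the update
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_sim import ChoiceNetwork, NetworkParams, build_network
from .psychometrics import ChoiceDataset, coherence, weibull_p
from .rt_analysis import RTSample

__all__ = [
    "SyntheticChoiceSpec",
    "SyntheticRTSpec",
    "gen_choices",
    "gen_rts",
    "toy_network",
]


@dataclass(frozen=True)
class SyntheticChoiceSpec:
    """Choices from a known Weibull observer comparing λ_A to
    λ_B ~ Uniform(λ_A, 2λ_A)."""

    alpha: float = 12.8
    beta: float = 1.31
    lambda_a: float = 6.0
    n_trials: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass(frozen=True)
class SyntheticRTSpec:
    """Gamma-distributed reaction times (shape/rate, optional shift in ms)."""

    shape: float = 4.0
    rate: float = 0.01
    n: int = 2000
    shift_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("shape and rate must be positive")


def gen_choices(spec: SyntheticChoiceSpec) -> ChoiceDataset:
    rng = np.random.default_rng(spec.seed)
    lam_b = rng.uniform(spec.lambda_a, 2.0 * spec.lambda_a, spec.n_trials)
    lam_a = np.full(spec.n_trials, spec.lambda_a)
    p = weibull_p(coherence(lam_a, lam_b), spec.alpha, spec.beta)
    correct = (rng.random(spec.n_trials) < p).astype(int)
    return ChoiceDataset(lam_a, lam_b, correct)


def gen_rts(spec: SyntheticRTSpec, lambda_a: float = 0.0,
            lambda_b: float = 0.0) -> RTSample:
    rng = np.random.default_rng(spec.seed)
    rts = rng.gamma(spec.shape, 1.0 / spec.rate, spec.n) + spec.shift_ms
    return RTSample(lambda_a=lambda_a, lambda_b=lambda_b, rts_ms=rts,
                    correct=np.ones(spec.n, bool))


TOY_SEED = 20240901


def toy_network() -> ChoiceNetwork:
    """Fixed 20-neuron circuit (pools of 3) for hand-checkable unit tests."""
    params = NetworkParams(N=20, n_pool=3, t_spontaneous_ms=100.0,
                           t_stimulus_ms=300.0)
    return build_network(params, TOY_SEED)
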