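"""Weber's-Law experiment: JND curves, noise adjustment, linearity/convexity.

For each reference intensity λ_A the circuit is run on comparisons against
λ_B drawn uniformly on (λ_A, 2·λ_A); a Weibull psychometric fit is inverted
at target choice probabilities p to estimate the intensity λ_B(p) the
observer distinguishes from λ_A with probability p.  The resulting increment
Δλ(p) = λ_B(p) − λ_A and Weber fraction Δλ(p)/λ_A are assembled into a curve
over λ_A, on which two regressions quantify the law:

* generalized Weber's Law — OLS of Δλ on λ_A (slope k, intercept);
* convexity — OLS of the Weber fraction on (1, λ_A, λ_A²); a significantly
  positive second-order coefficient marks the departure from a constant
  fraction (the ratio principle).

With background input noise λ_0 the fraction is reported against the
noise-free part of the signal: (λ_B − λ_A)/(λ_A − λ_0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .network_sim import NetworkParams, StimulusSpec, run_trials
from .psychometrics import (
    BootstrapCI,
    ChoiceDataset,
    FitError,
    PsychometricFit,
    bootstrap_ci,
    fit_weibull,
    lambda_b_at_p,
    weibull_quantile,
)

__all__ = [
    "WeberPoint",
    "WeberCurve",
    "ConvexityTest",
    "LinearFit",
    "simulate_choice_dataset",
    "run_weber_experiment",
    "weber_fraction",
    "noise_adjusted_fraction",
    "convexity_test",
    "generalized_weber_fit",
]


@dataclass
class WeberPoint:
    """λ_B(p) estimate and derived quantities at one reference intensity."""

    lambda_a: float
    p_target: float
    lambda_b_hat: float
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    lambda_0: float = 0.0

    @property
    def delta(self) -> float:
        return self.lambda_b_hat - self.lambda_a

    @property
    def fraction(self) -> float:
        return weber_fraction(self)

    @property
    def fraction_noise_adjusted(self) -> float:
        return noise_adjusted_fraction(self, self.lambda_0)


@dataclass
class WeberCurve:
    p_target: float
    points: list[WeberPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points.sort(key=lambda pt: pt.lambda_a)

    @property
    def lambda_a(self) -> np.ndarray:
        return np.array([pt.lambda_a for pt in self.points])

    @property
    def delta(self) -> np.ndarray:
        return np.array([pt.delta for pt in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([pt.fraction for pt in self.points])

    @property
    def fractions_noise_adjusted(self) -> np.ndarray:
        return np.array([pt.fraction_noise_adjusted for pt in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda_a": self.lambda_a,
            "p": self.p_target,
            "lambda_b_hat": [pt.lambda_b_hat for pt in self.points],
            "ci_lo": [pt.ci_lo for pt in self.points],
            "ci_hi": [pt.ci_hi for pt in self.points],
            "delta": self.delta,
            "fraction": self.fractions,
            "fraction_noise_adjusted": self.fractions_noise_adjusted,
        })


def weber_fraction(point, lambda_b: float | None = None) -> float:
    """Plain Weber fraction (λ_B − λ_A)/λ_A."""
    if lambda_b is None:
        lam_a, lam_b = point.lambda_a, point.lambda_b_hat
    else:
        lam_a, lam_b = float(point), lambda_b
    if lam_a <= 0:
        raise ValueError("lambda_A must be positive")
    return (lam_b - lam_a) / lam_a


def noise_adjusted_fraction(point, lambda_0: float,
                            lambda_b: float | None = None) -> float:
    """Weber fraction against the noise-free signal: (λ_B − λ_A)/(λ_A − λ_0)."""
    if lambda_b is None:
        lam_a, lam_b = point.lambda_a, point.lambda_b_hat
    else:
        lam_a, lam_b = float(point), lambda_b
    if lambda_0 < 0:
        raise ValueError("lambda_0 must be nonnegative")
    if lam_a <= lambda_0:
        raise ValueError("need lambda_A > lambda_0")
    return (lam_b - lam_a) / (lam_a - lambda_0)


# ---------------------------------------------------------------------------
# simulation orchestration


def simulate_choice_dataset(params: NetworkParams, lambda_a: float,
                            n_trials: int, rng_seed: int,
                            lambda_0: float = 0.0,
                            fresh_network: bool = True,
                            ) -> tuple[ChoiceDataset, int]:
    """Run comparison trials with λ_B ~ Uniform(λ_A, 2λ_A).

    Returns the decided-trial choice dataset (correct = chose B) and the
    number of undecided trials that were excluded.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 17]))
    lam_b = rng.uniform(lambda_a, 2.0 * lambda_a, n_trials)
    stims = [StimulusSpec(lambda_a, lb, lambda_0) for lb in lam_b]
    log = run_trials(params, stims, rng_seed, fresh_network=fresh_network)
    n_undecided = int((log["decision"] == "undecided").sum())
    return ChoiceDataset.from_frame(log), n_undecided


def run_weber_experiment(net_params: NetworkParams,
                         lambda_a_grid=tuple(range(2, 12)),
                         p_targets=(2.0 / 3.0, 0.75, 0.85),
                         trials_per_level: int = 5000,
                         rng_seed: int = 0,
                         lambda_0: float = 0.0,
                         n_boot: int = 1000,
                         fresh_network: bool = True,
                         ) -> dict[float, WeberCurve]:
    """Full Weber's-Law experiment; returns one curve per target probability.

    A level whose psychometric fit degenerates is dropped from every curve
    rather than aborting the run.
    """
    if trials_per_level < 100:
        raise ValueError("need at least 100 trials per level")
    for p in p_targets:
        if not 0.5 < p < 1.0:
            raise ValueError("target probabilities must lie in (0.5, 1)")
    ss = np.random.SeedSequence(rng_seed)
    curves = {p: WeberCurve(p) for p in p_targets}
    for lam_a, child in zip(lambda_a_grid, ss.spawn(len(lambda_a_grid))):
        sim_seed, boot_seed = child.generate_state(2)
        try:
            data, _ = simulate_choice_dataset(
                net_params, float(lam_a), trials_per_level, int(sim_seed),
                lambda_0=lambda_0, fresh_network=fresh_network)
            fit = fit_weibull(data)
        except FitError:
            continue
        for p in p_targets:
            c_hat = weibull_quantile(p, fit.alpha, fit.beta)
            lb_hat = lambda_b_at_p(float(lam_a), c_hat)
            ci = (np.nan, np.nan)
            if n_boot >= 2:
                ci = bootstrap_ci(data, p, n_boot=n_boot,
                                  seed=int(boot_seed)).lambda_b
            curves[p].points.append(WeberPoint(
                lambda_a=float(lam_a), p_target=p, lambda_b_hat=lb_hat,
                ci_lo=ci[0], ci_hi=ci[1], lambda_0=lambda_0))
    for curve in curves.values():
        curve.points.sort(key=lambda pt: pt.lambda_a)
    return curves


# ---------------------------------------------------------------------------
# regression tests of the law


@dataclass
class ConvexityTest:
    a0: float
    a1: float
    a2: float
    t_value: float
    p_value: float


@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float


def convexity_test(curve: WeberCurve, noise_adjusted: bool = False) -> ConvexityTest:
    """OLS of the Weber fraction on (1, λ_A, λ_A²); t-test of the quadratic
    coefficient (two-sided, n − 3 df)."""
    x = curve.lambda_a
    if len(x) < 4:
        raise ValueError("need at least 4 points for the convexity test")
    y = curve.fractions_noise_adjusted if noise_adjusted else curve.fractions
    X = np.column_stack([np.ones_like(x), x, x ** 2])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    return ConvexityTest(a0=res.params[0], a1=res.params[1], a2=res.params[2],
                         t_value=float(res.tvalues[2]),
                         p_value=float(res.pvalues[2]))


def generalized_weber_fit(curve: WeberCurve) -> LinearFit:
    """OLS of Δλ(p) on λ_A: slope is the Weber fraction k, a nonzero
    intercept is the generalized-law constant."""
    x = curve.lambda_a
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("design matrix is rank deficient")
    X = sm.add_constant(x)
    res = sm.OLS(curve.delta, X).fit()
    return LinearFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                     slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]))
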