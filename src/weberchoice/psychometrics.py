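"""Weibull psychometric estimation for two-alternative choices.

The probability of a correct choice as a function of coherence
``c = 100·(λ_B − λ_A)/(λ_A + λ_B)`` (in percent) is modelled by the Weibull
psychometric function used throughout random-dot-motion psychophysics:

    p(c) = 1 − ½·exp(−(c/α)^β)

α is the coherence (in %) at which p ≈ 0.816, β controls the slope.  The fit
is by maximum likelihood on per-trial Bernoulli outcomes; the function is
inverted analytically to read off the coherence — and from it the stimulus
intensity λ_B — that yields a target choice probability p, with percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ChoiceDataset",
    "PsychometricFit",
    "FitError",
    "coherence",
    "weibull_p",
    "fit_weibull",
    "invert_weibull",
    "weibull_quantile",
    "lambda_b_at_p",
    "bootstrap_ci",
    "BootstrapCI",
]


class FitError(RuntimeError):
    """Raised when the psychometric likelihood has no interior maximum."""


def coherence(lambda_A, lambda_B):
    """Coherence in percent: 100·(λ_B − λ_A)/(λ_A + λ_B)."""
    lambda_A = np.asarray(lambda_A, float)
    lambda_B = np.asarray(lambda_B, float)
    total = lambda_A + lambda_B
    if np.any(total <= 0):
        raise ValueError("lambda_A + lambda_B must be positive")
    out = 100.0 * (lambda_B - lambda_A) / total
    return float(out) if out.ndim == 0 else out


def weibull_p(c, alpha: float, beta: float):
    """Probability of a correct choice at coherence ``c`` (percent)."""
    c = np.asarray(c, float)
    with np.errstate(over="ignore"):  # (c/alpha)**beta -> inf is fine: p -> 1
        out = 1.0 - 0.5 * np.exp(-((c / alpha) ** beta))
    return float(out) if out.ndim == 0 else out


def weibull_quantile(p: float, alpha: float, beta: float) -> float:
    """Coherence (percent) at which the Weibull psychometric reaches ``p``."""
    if not 0.5 < p < 1.0:
        raise ValueError("target probability must lie in (0.5, 1)")
    return alpha * (-np.log(2.0 * (1.0 - p))) ** (1.0 / beta)


def lambda_b_at_p(lambda_A: float, c: float) -> float:
    """Stimulus intensity λ_B at coherence ``c`` percent, given λ_A."""
    if c >= 100.0:
        raise ValueError("coherence must be below 100%")
    return lambda_A * (1.0 + c / 100.0) / (1.0 - c / 100.0)


@dataclass
class ChoiceDataset:
    """Binary choice records: (λ_A, λ_B, correct) per trial."""

    lambda_a: np.ndarray
    lambda_b: np.ndarray
    correct: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_a = np.asarray(self.lambda_a, float)
        self.lambda_b = np.asarray(self.lambda_b, float)
        self.correct = np.asarray(self.correct, int)
        if not (len(self.lambda_a) == len(self.lambda_b) == len(self.correct)):
            raise ValueError("field lengths differ")
        if not np.isin(self.correct, (0, 1)).all():
            raise ValueError("correct must be binary")

    def __len__(self) -> int:
        return len(self.correct)

    @property
    def coherence(self) -> np.ndarray:
        return coherence(self.lambda_a, self.lambda_b)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceDataset":
        """Build from a simulator trial log (``decision`` column; undecided
        trials dropped, correct = chose B) or from a ``correct``-column
        table."""
        if "decision" in df.columns:
            dec = df[df["decision"].isin(["A", "B"])]
            correct = (dec["decision"] == "B").astype(int).to_numpy()
        else:
            dec = df
            correct = dec["correct"].to_numpy()
        return cls(dec["lambda_a"].to_numpy(), dec["lambda_b"].to_numpy(),
                   correct)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda_a": self.lambda_a,
                             "lambda_b": self.lambda_b,
                             "correct": self.correct})

    def subset(self, idx) -> "ChoiceDataset":
        return ChoiceDataset(self.lambda_a[idx], self.lambda_b[idx],
                             self.correct[idx])


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    loglik: float
    n_trials: int
    bootstrap_replicates: np.ndarray | None = field(default=None, repr=False)


def _nll(log_params: np.ndarray, c: np.ndarray, y: np.ndarray) -> float:
    alpha, beta = np.exp(log_params)
    p = weibull_p(c, alpha, beta)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(y @ np.log(p) + (1 - y) @ np.log1p(-p))


def fit_weibull(data: ChoiceDataset) -> PsychometricFit:
    """Maximum-likelihood Weibull fit to per-trial binary outcomes.

    Zero-coherence trials carry no information under this likelihood
    (p ≡ 0.5) and are dropped.  Optimization runs in log-parameter space
    from several starts: α₀ at the empirical 75%-correct coherence, β₀ = 1.
    Degenerate data (single outcome class) and boundary solutions raise
    :class:`FitError`.
    """
    c = data.coherence
    y = data.correct
    keep = c > 0
    c, y = c[keep], y[keep]
    if len(c) < 3:
        raise FitError("too few informative (c > 0) trials")
    if y.min() == y.max():
        raise FitError("all outcomes identical; likelihood is unbounded")
    if len(np.unique(c)) < 2:
        raise FitError("a single coherence level cannot identify (alpha, beta)")

    # empirical alpha start: coherence around which accuracy crosses 75%
    order = np.argsort(c)
    cum = np.cumsum(y[order]) / np.arange(1, len(y) + 1)
    above = np.flatnonzero(cum[len(cum) // 4:] >= 0.75)
    alpha0 = c[order][len(cum) // 4 + above[0]] if len(above) else np.median(c)
    alpha0 = max(alpha0, 1e-3)

    best = None
    for a0, b0 in ((alpha0, 1.0), (np.median(c), 1.0), (alpha0, 2.0)):
        res = optimize.minimize(_nll, np.log([a0, b0]), args=(c, y),
                                method="L-BFGS-B",
                                bounds=[(-10.0, 12.0), (-4.0, 4.0)])
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not best.success:
        raise FitError(f"optimizer failed: {best.message if best else 'no fit'}")
    la, lb = best.x
    if not (-9.5 < la < 11.5 and -3.9 < lb < 3.9):
        raise FitError("boundary estimate; data do not constrain the fit")
    alpha, beta = float(np.exp(la)), float(np.exp(lb))
    return PsychometricFit(alpha=alpha, beta=beta, loglik=-float(best.fun),
                           n_trials=int(len(c)))


def invert_weibull(fit, p: float, beta: float | None = None) -> float:
    """Coherence (percent) at which the fitted psychometric reaches ``p``.

    ``fit`` may be a :class:`PsychometricFit` or a bare α (with β passed as
    the third argument).
    """
    if beta is not None:
        alpha = float(fit)
    else:
        alpha, beta = fit.alpha, fit.beta
    return weibull_quantile(p, alpha, beta)


@dataclass
class BootstrapCI:
    lambda_b: tuple[float, float]
    fraction: tuple[float, float]
    replicates_lambda_b: np.ndarray
    n_refit_failures: int


def bootstrap_ci(data: ChoiceDataset, p: float, n_boot: int = 1000,
                 level: float = 0.95, seed: int | None = None,
                 lambda_0: float = 0.0) -> BootstrapCI:
    """Percentile bootstrap interval for λ_B(p) and the Weber fraction.

    Trials are resampled with replacement and the fit/inversion repeated;
    resamples on which the fit degenerates are redrawn (their count is
    reported).  The fraction interval is the endpoint transform of the λ_B
    interval, using the (noise-adjusted when ``lambda_0 > 0``) denominator.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    la_vals = np.unique(data.lambda_a)
    if len(la_vals) != 1:
        raise ValueError("bootstrap_ci expects a single lambda_A condition")
    lam_a = float(la_vals[0])
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.empty(n_boot)
    failures = 0
    k = 0
    while k < n_boot:
        idx = rng.integers(0, n, n)
        try:
            fit = fit_weibull(data.subset(idx))
        except FitError:
            failures += 1
            if failures > 50 * n_boot:
                raise FitError("bootstrap refits keep failing; data degenerate")
            continue
        reps[k] = lambda_b_at_p(lam_a, weibull_quantile(p, fit.alpha, fit.beta))
        k += 1
    lo, hi = np.quantile(reps, [(1 - level) / 2, (1 + level) / 2])
    denom = lam_a - lambda_0
    return BootstrapCI(lambda_b=(float(lo), float(hi)),
                       fraction=((lo - lam_a) / denom, (hi - lam_a) / denom),
                       replicates_lambda_b=reps, n_refit_failures=failures)
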