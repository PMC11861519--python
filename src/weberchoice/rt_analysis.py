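"""Reaction-time distribution analysis and scale-invariance testing.

Scale invariance of RT distributions predicts that, at a constant Weber
fraction, the RT distributions at different reference intensities coincide
after a pure rescaling of time — implying equal skewness, kurtosis and (for a
gamma family) shape.  The test used here rescales each distribution by the
inverse of its median, then searches a small correcting factor γ minimizing
the two-sample Kolmogorov–Smirnov statistic against a reference distribution;
residual differences are probed by the K-S test and by unbiased skewness /
kurtosis estimators (the sample-size-corrected estimators standard in
Cullen–Frey analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RTSample",
    "ScaleInvarianceReport",
    "simulate_rt_sample",
    "rt_contrast",
    "rescale_to_reference",
    "select_reference",
    "skewness_unbiased",
    "kurtosis_unbiased",
    "cullen_frey_point",
    "gamma_skewness_curve",
    "gamma_fit",
    "skewness_ci",
    "scale_invariance_report",
]

GAMMA_SEARCH = (0.90, 1.10)
GAMMA_STEP = 1e-4


@dataclass
class RTSample:
    """Decision latencies for one (λ_A, λ_B) condition."""

    lambda_a: float
    lambda_b: float
    rts_ms: np.ndarray
    correct: np.ndarray          # bool per RT
    n_undecided: int = 0

    def __post_init__(self) -> None:
        self.rts_ms = np.asarray(self.rts_ms, float)
        self.correct = np.asarray(self.correct, bool)
        if len(self.rts_ms) != len(self.correct):
            raise ValueError("labels must match rts in length")
        if np.any(self.rts_ms <= 0):
            raise ValueError("reaction times must be positive")

    def __len__(self) -> int:
        return len(self.rts_ms)

    def pooled(self) -> np.ndarray:
        return self.rts_ms


def simulate_rt_sample(params, lambda_a: float, lambda_b: float,
                       n_trials: int, rng_seed: int, lambda_0: float = 0.0,
                       fresh_network: bool = True) -> RTSample:
    """Run trials at a fixed (λ_A, λ_B) pair and collect decision latencies.

    Undecided trials are excluded from the sample (their count is kept);
    ``correct`` marks decisions for the higher-intensity alternative B.
    """
    from .network_sim import StimulusSpec, run_trials

    stims = [StimulusSpec(lambda_a, lambda_b, lambda_0)] * n_trials
    log = run_trials(params, stims, rng_seed, fresh_network=fresh_network)
    dec = log[log.decision != "undecided"]
    return RTSample(lambda_a=lambda_a, lambda_b=lambda_b,
                    rts_ms=dec.rt_ms.to_numpy(),
                    correct=(dec.decision == "B").to_numpy(),
                    n_undecided=int(len(log) - len(dec)))


def rt_contrast(sample: RTSample) -> tuple[float, float, float]:
    """Mean RT of correct and erroneous decisions and their difference
    (error − correct), in ms."""
    rts, ok = sample.rts_ms, sample.correct
    if ok.all() or (~ok).all():
        raise ValueError("need both correct and error trials")
    mean_correct = float(rts[ok].mean())
    mean_error = float(rts[~ok].mean())
    return mean_correct, mean_error, mean_error - mean_correct


# ---------------------------------------------------------------------------
# K-S rescaling


def _ks_statistic(x_sorted: np.ndarray, y_sorted: np.ndarray) -> float:
    """Two-sample K-S statistic D = sup |F_x − F_y|.

    ECDFs are evaluated with right-continuous searchsorted on the union of
    jump points, which is exact in the presence of ties (simulated RTs are
    tied on the rate-sampling grid).
    """
    grid = np.concatenate([x_sorted, y_sorted])
    fx = np.searchsorted(x_sorted, grid, side="right") / len(x_sorted)
    fy = np.searchsorted(y_sorted, grid, side="right") / len(y_sorted)
    return float(np.abs(fx - fy).max())


def rescale_to_reference(sample, reference) -> tuple[float, float, float]:
    """Median-rescale both samples, then find the correcting factor γ.

    Both inputs (arrays or :class:`RTSample`, pooled over correct/error) are
    divided by their own medians; γ is searched on the grid
    [0.90, 1.10] step 1e-4 to minimize the K-S statistic between γ·sample and
    the reference (the statistic is piecewise constant, so the grid resolves
    it exactly for practical sample sizes).  Returns (γ, D at γ, asymptotic
    two-sample K-S p-value at γ).
    """
    x = np.asarray(sample.pooled() if isinstance(sample, RTSample) else sample,
                   float)
    r = np.asarray(reference.pooled() if isinstance(reference, RTSample)
                   else reference, float)
    if len(x) == 0 or len(r) == 0:
        raise ValueError("samples must be nonempty")
    xs = np.sort(x / np.median(x))
    rs = np.sort(r / np.median(r))
    # integer grid keeps gamma = 1 exactly representable
    denom = int(round(1.0 / GAMMA_STEP))
    gammas = np.arange(int(GAMMA_SEARCH[0] * denom),
                       int(GAMMA_SEARCH[1] * denom) + 1) / denom
    best_gamma, best_d = 1.0, np.inf
    for g in gammas:
        d = _ks_statistic(xs * g, rs)
        if d < best_d - 1e-15:
            best_d, best_gamma = d, float(g)
    p = float(stats.ks_2samp(xs * best_gamma, rs, method="asymp").pvalue)
    return best_gamma, best_d, p


def select_reference(samples: dict) -> float:
    """Pick the reference level minimizing the summed minimized K-S statistic
    against all other levels; ties go to the lowest level."""
    levels = sorted(samples)
    if len(levels) < 2:
        raise ValueError("need at least two levels")
    best_level, best_total = None, np.inf
    for ref in levels:
        total = 0.0
        for lev in levels:
            if lev == ref:
                continue
            _, d, _ = rescale_to_reference(samples[lev], samples[ref])
            total += d
        if total < best_total - 1e-12:
            best_total, best_level = total, ref
    return best_level


# ---------------------------------------------------------------------------
# shape statistics

# These are the sample-size-corrected ("unbiased") skewness and Pearson
# kurtosis estimators used by Cullen-Frey diagnostics (fitdistrplus::descdist
# in R); both are invariant under x -> c*x for c > 0.


def _moments(x: np.ndarray) -> tuple[int, float, float, float, float]:
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    dev = x - xbar
    m2 = float((dev ** 2).mean())
    m3 = float((dev ** 3).mean())
    m4 = float((dev ** 4).mean())
    return n, xbar, m2, m3, m4


def skewness_unbiased(x) -> float:
    """G1 = √(n(n−1))/(n−2) · m₃/m₂^{3/2}."""
    n, _, m2, m3, _ = _moments(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if m2 == 0:
        raise ValueError("zero variance")
    return np.sqrt(n * (n - 1.0)) / (n - 2.0) * m3 / m2 ** 1.5


def kurtosis_unbiased(x) -> float:
    """Pearson kurtosis (normal → 3):
    (n−1)/((n−2)(n−3)) · ((n+1)·m₄/m₂² − 3(n−1)) + 3."""
    n, _, m2, _, m4 = _moments(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if m2 == 0:
        raise ValueError("zero variance")
    return (n - 1.0) / ((n - 2.0) * (n - 3.0)) * (
        (n + 1.0) * m4 / m2 ** 2 - 3.0 * (n - 1.0)) + 3.0


def cullen_frey_point(x) -> tuple[float, float]:
    """Coordinates (skewness², Pearson kurtosis) on the Cullen–Frey graph."""
    return skewness_unbiased(x) ** 2, kurtosis_unbiased(x)


def gamma_skewness_curve(sk_squared) -> np.ndarray | float:
    """Gamma-family reference line on the Cullen–Frey graph.

    For gamma(shape α): skewness 2/√α and excess kurtosis 6/α, hence
    kurtosis = 3 + 1.5·skewness².
    """
    return 3.0 + 1.5 * np.asarray(sk_squared, float)


def gamma_fit(x) -> tuple[float, float]:
    """Maximum-likelihood gamma (shape, rate) for a positive sample."""
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("gamma fit requires positive values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance")
    shape, _, scale = stats.gamma.fit(x, floc=0.0)
    return float(shape), 1.0 / float(scale)


def skewness_ci(x, n_boot: int = 10000, level: float = 0.95,
                seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap interval for the unbiased skewness."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, (n_boot, n))
    samples = x[idx]
    dev = samples - samples.mean(axis=1, keepdims=True)
    m2 = (dev ** 2).mean(axis=1)
    m3 = (dev ** 3).mean(axis=1)
    g1 = np.sqrt(n * (n - 1.0)) / (n - 2.0) * m3 / m2 ** 1.5
    lo, hi = np.quantile(g1, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# report


@dataclass
class LevelReport:
    lambda_a: float
    n: int
    correcting_factor: float
    ks_d: float
    ks_p: float
    skewness: float
    skewness_ci: tuple[float, float]
    kurtosis: float
    gamma_shape: float
    gamma_rate: float


@dataclass
class ScaleInvarianceReport:
    reference_level: float
    levels: list[LevelReport] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reference_level": self.reference_level,
            "levels": [vars(l) | {"skewness_ci": list(l.skewness_ci)}
                       for l in self.levels],
        }


def scale_invariance_report(samples: dict[float, RTSample],
                            reference: float | str = "auto",
                            n_boot: int = 10000,
                            seed: int | None = None) -> ScaleInvarianceReport:
    """Full scale-invariance battery over per-level RT samples.

    Correct and error RTs are pooled.  ``reference`` may be a level or
    ``"auto"`` (minimize the summed K-S statistic).
    """
    if reference == "auto":
        reference = select_reference(samples)
    ref = samples[reference]
    ss = np.random.SeedSequence(seed)
    report = ScaleInvarianceReport(reference_level=reference)
    for (lev, child) in zip(sorted(samples), ss.spawn(len(samples))):
        s = samples[lev]
        gamma, d, p = rescale_to_reference(s, ref)
        shape, rate = gamma_fit(s.pooled())
        report.levels.append(LevelReport(
            lambda_a=lev, n=len(s), correcting_factor=gamma, ks_d=d, ks_p=p,
            skewness=skewness_unbiased(s.pooled()),
            skewness_ci=skewness_ci(s.pooled(), n_boot=n_boot,
                                    seed=int(child.generate_state(1)[0])),
            kurtosis=kurtosis_unbiased(s.pooled()),
            gamma_shape=shape, gamma_rate=rate))
    return report
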