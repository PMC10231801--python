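"""The three observation families of the symptom trajectory model.

Every measure j enters the model through a linear predictor

    eta_ijt = alpha_j + beta_j1 * Age_it + beta_j2 * Rate_i * [Age_it - Onset_i]+

where [x]+ = max(x, 0) is the time since onset (zero for gene-negative
subjects and before onset). Ordinal measures use a cumulative logit model
with K-1 strictly increasing thresholds, positive reals a log-normal
regression, and counts a Poisson regression with a softplus mean scaled by
an exposure offset (1 for lip strength, the paired task duration for DDK
counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "OrdinalParams",
    "ContinuousParams",
    "CountParams",
    "time_since_onset",
    "softplus",
    "ordinal_category_probs",
    "ordinal_loglik",
    "continuous_loglik",
    "count_mean",
    "count_loglik",
]


def time_since_onset(age, onset):
    """Positive-part realigned time [age - onset]+ in years."""
    return np.maximum(np.asarray(age, dtype=float) - onset, 0.0)


def softplus(x):
    """Overflow-safe log(1 + exp(x)), strictly positive for finite x."""
    x = np.asarray(x, dtype=float)
    out = np.logaddexp(0.0, x)
    # guard the count-model mean against exact underflow to 0
    return np.maximum(out, np.finfo(float).tiny)


@dataclass(frozen=True)
class OrdinalParams:
    """Cumulative-logit parameters: thresholds a_1 < ... < a_{K-1}, slopes."""

    thresholds: tuple[float, ...]
    beta_age: float
    beta_rate: float

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) < 1 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing, length K-1 >= 1")


@dataclass(frozen=True)
class ContinuousParams:
    """Log-normal regression parameters."""

    alpha: float
    beta_age: float
    beta_rate: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class CountParams:
    """Poisson regression with softplus mean and exposure offset."""

    alpha: float
    beta_age: float
    beta_rate: float


def _linpred(alpha, beta_age, beta_rate, age, rate, onset):
    return alpha + beta_age * np.asarray(age, float) + beta_rate * rate * time_since_onset(age, onset)


def ordinal_category_probs(params: OrdinalParams, levels, age, rate, onset) -> np.ndarray:
    """Per-category probabilities of a cumulative logit model.

    P(Y <= c_k) = logistic(a_k + beta1*age + beta2*rate*[age-onset]+) for
    k = 1..K-1, with the K-th cumulative probability fixed at 1; category
    probabilities are successive differences.
    """
    levels = np.asarray(levels, dtype=float)
    K = levels.size
    if len(params.thresholds) != K - 1:
        raise ValueError(f"need K-1={K - 1} thresholds, got {len(params.thresholds)}")
    shift = params.beta_age * float(age) + params.beta_rate * rate * float(
        time_since_onset(age, onset)
    )
    cum = special.expit(np.asarray(params.thresholds) + shift)
    cum = np.concatenate([[0.0], np.maximum.accumulate(cum), [1.0]])
    return np.diff(cum)


def ordinal_loglik(params: OrdinalParams, levels, value, age, rate, onset) -> float:
    """Log probability of an observed ordinal category value."""
    levels = list(np.asarray(levels, dtype=float))
    if float(value) not in levels:
        raise ValueError(f"value {value} not an ordinal level")
    p = ordinal_category_probs(params, levels, age, rate, onset)
    return float(np.log(np.maximum(p[levels.index(float(value))], 1e-300)))


def continuous_loglik(params: ContinuousParams, value, age, rate, onset) -> float:
    """Log density of a positive real observation under log-normal regression.

    log(Y) ~ Normal(mu, sigma) with mu the linear predictor; the returned
    density is for Y itself (includes the 1/Y Jacobian).
    """
    value = float(value)
    if value <= 0:
        raise ValueError("positive_real value must be > 0")
    mu = _linpred(params.alpha, params.beta_age, params.beta_rate, age, rate, onset)
    return float(stats.norm.logpdf(np.log(value), loc=mu, scale=params.sigma) - np.log(value))


def count_mean(params: CountParams, offset, age, rate, onset) -> float:
    """Poisson mean offset * softplus(linear predictor); offset must be > 0."""
    offset = float(offset)
    if offset <= 0:
        raise ValueError("offset must be > 0")
    eta = _linpred(params.alpha, params.beta_age, params.beta_rate, age, rate, onset)
    return float(offset * softplus(eta))


def count_loglik(params: CountParams, value, offset, age, rate, onset) -> float:
    """Poisson log pmf of a non-negative integer observation."""
    value = float(value)
    if value < 0 or value != int(value):
        raise ValueError("count value must be a non-negative integer")
    lam = count_mean(params, offset, age, rate, onset)
    return float(stats.poisson.logpmf(int(value), lam))
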