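"""Probability-of-disease curves from PRS group moments and prevalence.

Given the PRS mean/variance in cases (m1, sigma1^2) and non-cases
(m0, sigma0^2) and the disease prevalence K, Bayesian inversion of the two
normal densities gives a raw posterior probability of being a case at each
score value.  Its logit is exactly affine in the score when the two group
variances are equal; in general it is quadratic, and the calibrated model is
the density-weighted linear (logit-link) projection, whose coefficients
admit a closed form:

    beta  = (m1 - m0)/sigma_p^2 * ( K(1-K)((r0 + r1)/2 - 1)
                                    + K sigma1^2/sigma0^2
                                    + (1-K) sigma0^2/sigma1^2 )
    alpha = log( K sigma0 / ((1-K) sigma1) )
            + 1/2 ( (r0 - 1) K + (1 - r1)(1 - K) ) - m_p beta

with r0 = (sigma1^2 + (m1-m0)^2)/sigma0^2, r1 = (sigma0^2 + (m1-m0)^2)/sigma1^2
and (m_p, sigma_p^2) the population mixture moments.  This dispenses with
individual-level genotypes entirely: five summary numbers produce the whole
logistic curve P(x) = 1/(1 + exp(-(alpha + beta x))).

All density work is done in log space; the raw probability is formed through
a log-odds difference and the logistic function, so the curve is finite and
monotone even ten standard deviations into the tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .prs_core import GroupMoments, mixture_moments

__all__ = [
    "LogisticCurve",
    "CurveTable",
    "GridSpec",
    "raw_probability",
    "raw_log_odds",
    "closed_form_coefficients",
    "logistic_probability",
    "probability_curve",
]


def _check_inputs(cases: GroupMoments, noncases: GroupMoments, K: float) -> None:
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    if cases.variance <= 0 or noncases.variance <= 0:
        raise ValueError("group variances must be positive")


@dataclass(frozen=True)
class LogisticCurve:
    """Calibrated logistic curve P(x) = expit(alpha + beta x) with provenance."""

    alpha: float
    beta: float
    prevalence: float
    cases: GroupMoments
    noncases: GroupMoments

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("curve coefficients must be finite")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")

    @property
    def population(self) -> GroupMoments:
        return mixture_moments(self.cases, self.noncases, self.prevalence)

    @property
    def m_p(self) -> float:
        return self.population.mean

    @property
    def sigma_p2(self) -> float:
        return self.population.variance

    @property
    def r0(self) -> float:
        d = self.cases.mean - self.noncases.mean
        return (self.cases.variance + d * d) / self.noncases.variance

    @property
    def r1(self) -> float:
        d = self.cases.mean - self.noncases.mean
        return (self.noncases.variance + d * d) / self.cases.variance


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grid on the standardised (population SD) axis."""

    lo: float = -4.0
    hi: float = 4.0
    n: int = 161

    def __post_init__(self) -> None:
        if not (self.lo < self.hi) or self.n < 2:
            raise ValueError("grid requires lo < hi and n >= 2")

    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)


@dataclass
class CurveTable:
    """Tabulated probability curve on a standardised PRS grid."""

    x_st: np.ndarray
    probability: np.ndarray
    raw_probability: Optional[np.ndarray] = None
    curve: Optional[LogisticCurve] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x_st = np.asarray(self.x_st, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if np.any(np.diff(self.x_st) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def raw_log_odds(x, cases: GroupMoments, noncases: GroupMoments, K: float):
    """Log odds of disease at PRS x from Bayesian inversion of normal densities.

    y(x) = log( K p1(x) / ((1-K) p0(x)) ), evaluated via log-densities so the
    tails never overflow.  Affine in x iff the group variances coincide.
    """
    _check_inputs(cases, noncases, K)
    x = np.asarray(x, dtype=float)
    y = (
        np.log(K / (1.0 - K))
        + norm.logpdf(x, cases.mean, cases.sd)
        - norm.logpdf(x, noncases.mean, noncases.sd)
    )
    return float(y) if y.ndim == 0 else y


def raw_probability(x, cases: GroupMoments, noncases: GroupMoments, K: float):
    """Posterior probability of disease at PRS x.

    P_hat(x) = K p1(x) / (K p1(x) + (1-K) p0(x)), computed as
    expit(raw_log_odds) for numerical stability.
    """
    out = expit(raw_log_odds(x, cases, noncases, K))
    return float(out) if np.ndim(out) == 0 else out


def closed_form_coefficients(
    cases: GroupMoments, noncases: GroupMoments, K: float
) -> LogisticCurve:
    """Closed-form logistic coefficients from group moments and prevalence."""
    _check_inputs(cases, noncases, K)
    m1, v1 = cases.mean, cases.variance
    m0, v0 = noncases.mean, noncases.variance
    d = m1 - m0
    r0 = (v1 + d * d) / v0
    r1 = (v0 + d * d) / v1
    pop = mixture_moments(cases, noncases, K)
    beta = (d / pop.variance) * (
        K * (1.0 - K) * ((r0 + r1) / 2.0 - 1.0) + K * v1 / v0 + (1.0 - K) * v0 / v1
    )
    alpha = (
        np.log(K * np.sqrt(v0) / ((1.0 - K) * np.sqrt(v1)))
        + 0.5 * ((r0 - 1.0) * K + (1.0 - r1) * (1.0 - K))
        - pop.mean * beta
    )
    return LogisticCurve(float(alpha), float(beta), K, cases, noncases)


def logistic_probability(curve: LogisticCurve, x):
    """Evaluate the logistic model P(x) = 1/(1 + exp(-(alpha + beta x)))."""
    out = expit(curve.alpha + curve.beta * np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def probability_curve(
    curve: LogisticCurve,
    population: Optional[GroupMoments] = None,
    grid: GridSpec = GridSpec(),
    include_raw: bool = True,
) -> CurveTable:
    """Tabulate the curve on a standardised grid.

    The grid lives on the standardised axis; each point x_st is mapped back to
    the raw score x = m_p + x_st * sigma_p before evaluation.  Defaults to the
    population moments implied by the curve's own source moments.
    """
    pop = population if population is not None else curve.population
    x_st = grid.points()
    x = pop.mean + x_st * pop.sd
    prob = logistic_probability(curve, x)
    raw = (
        raw_probability(x, curve.cases, curve.noncases, curve.prevalence)
        if include_raw
        else None
    )
    return CurveTable(x_st, prob, raw, curve)
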