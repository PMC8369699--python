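"""Genotype-stratified prevalences for a common high-effect variant.

A common high-effect risk allele like APOE-e4 shifts the disease prevalence
so strongly that the rare-variant treatment (which assumes K unchanged) does
not apply.  Instead, the population prevalence K is split into per-genotype
prevalences K0 (non-risk homozygote), K1 (heterozygote) and K2 (risk
homozygote), assuming Hardy-Weinberg equilibrium both in the population (at
risk-allele frequency f) and in the non-case subpopulation.  With the
auxiliary parameter

    nu = (b - sqrt(b^2 - 16 (1-OR)(1-f) K)) / (4 (1-OR)),
    b  = 2 (1 + (1-OR)(K - f)),

the genotype prevalences are

    K0 = 1 - (1-f-nu)^2           / ((1-K)(1-f)^2)
    K1 = 1 - (1-f-nu)(nu+f-K)     / ((1-K) f (1-f))
    K2 = 1 - (nu+f-K)^2           / ((1-K) f^2)

and satisfy (1-f)^2 K0 + 2 f(1-f) K1 + f^2 K2 = K exactly.  Geometrically,
nu encodes the non-case risk-allele frequency f0 = (f + nu - K)/(1-K); the
closed form is the root of the quadratic linking (K, f, OR) to f0 under the
allelic odds-ratio definition OR = odds(f1)/odds(f0).

Because the PRS computed *without* the variant's region can be assumed to
have the same distribution in every genotype stratum, per-genotype
probability curves are obtained simply by re-running the closed-form
calibration with K replaced by K0, K1, K2.

The HWE-in-non-cases approximation is good for low-prevalence diseases
(a few percent) and degrades as K grows.  Only the biallelic risk-allele
treatment is modelled; protective alleles (APOE-e2) and three-allele
genotype systems are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .prs_core import GroupMoments
from .risk_model import LogisticCurve, closed_form_coefficients

# |OR - 1| below this switches to the analytic limit nu = K(1-f)
# (removable singularity: the closed form divides by 1-OR).
_OR_ONE_TOLERANCE = 1e-8

__all__ = [
    "HighEffectVariant",
    "GenotypePrevalence",
    "solve_nu",
    "genotype_prevalences",
    "stratified_curves",
]


@dataclass(frozen=True)
class HighEffectVariant:
    """A common high-effect risk variant (risk-allele frequency and odds ratio)."""

    name: str
    risk_allele_frequency: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 < self.risk_allele_frequency < 1.0):
            raise ValueError("risk allele frequency must lie in (0, 1)")
        if self.odds_ratio <= 0.0:
            raise ValueError("odds ratio must be positive")


@dataclass(frozen=True)
class GenotypePrevalence:
    """Prevalences for the three genotypes of a biallelic variant."""

    K0: float  # non-risk homozygote
    K1: float  # heterozygote
    K2: float  # risk homozygote

    def __post_init__(self) -> None:
        for name, k in (("K0", self.K0), ("K1", self.K1), ("K2", self.K2)):
            if not (0.0 <= k <= 1.0):
                raise ValueError(
                    "model assumptions violated (prevalence too high for HWE "
                    f"approximation): {name} = {k:.6g}"
                )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.K0, self.K1, self.K2)


def solve_nu(K: float, f: float, OR: float) -> float:
    """Auxiliary frequency-shift parameter nu linking (K, f, OR) to genotype prevalences.

    Takes the minus-root branch of the quadratic; at OR = 1 the formula has a
    removable singularity and the analytic limit nu = K(1-f) is returned.
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    if not (0.0 < f < 1.0):
        raise ValueError(f"risk allele frequency must lie in (0, 1), got {f}")
    if OR <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {OR}")
    if abs(OR - 1.0) < _OR_ONE_TOLERANCE:
        return K * (1.0 - f)
    b = 2.0 * (1.0 + (1.0 - OR) * (K - f))
    disc = b * b - 16.0 * (1.0 - OR) * (1.0 - f) * K
    if disc < 0.0:
        raise ValueError(
            f"no real solution; inconsistent (K={K}, f={f}, OR={OR})"
        )
    return (b - np.sqrt(disc)) / (4.0 * (1.0 - OR))


def genotype_prevalences(K: float, f: float, OR: float) -> GenotypePrevalence:
    """Per-genotype prevalences (K0, K1, K2) under HWE in population and non-cases.

    Conserves overall prevalence exactly:
    (1-f)^2 K0 + 2 f(1-f) K1 + f^2 K2 = K.
    """
    nu = solve_nu(K, f, OR)
    a = 1.0 - f - nu       # (1-K) * (1 - f0), f0 = non-case risk allele freq
    c = nu + f - K         # (1-K) * f0
    K0 = 1.0 - a * a / ((1.0 - K) * (1.0 - f) ** 2)
    K1 = 1.0 - a * c / ((1.0 - K) * f * (1.0 - f))
    K2 = 1.0 - c * c / ((1.0 - K) * f * f)
    return GenotypePrevalence(K0, K1, K2)


def stratified_curves(
    cases: GroupMoments,
    noncases: GroupMoments,
    K: float,
    f: float,
    OR: float,
) -> tuple[LogisticCurve, LogisticCurve, LogisticCurve]:
    """One probability curve per genotype of a high-effect variant.

    The supplied moments must describe a PRS computed *excluding* the
    variant's region; the stratified curves then share those moments and
    differ only through the genotype prevalences.
    """
    kg = genotype_prevalences(K, f, OR)
    return tuple(
        closed_form_coefficients(cases, noncases, k) for k in kg.as_tuple()
    )  # type: ignore[return-value]
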