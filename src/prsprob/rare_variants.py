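"""Rare high-penetrance variants as an intrinsic probability layer.

Rare risk variants (e.g. in TREM2, SORL1, or near-fully-penetrant APP/PSEN
mutations) are poorly captured by a PRS: one strong allele drowns in the sum
of thousands of weak ones.  Provided the variant is rare enough not to move
the population prevalence K and acts independently of the polygenic
background, it can instead be given an intrinsic probability of causing
disease,

    p_rare = K (OR - 1) / (K (OR - 1) + 1),

and combined with the PRS-based curve as the union of independent causes:

    P(x) = P_PRS(x) + p_rare (1 - P_PRS(x)).

The combined curve runs from p_rare (at very low PRS) up to 1 — a carrier
retains the variant's risk even with the most protective polygenic
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# "very rare" is qualitative in the model; above this carrier-allele
# frequency the fixed-K assumption becomes questionable and we warn.
RARE_FREQUENCY_WARNING = 0.005

__all__ = [
    "RareVariant",
    "intrinsic_probability",
    "combine_intrinsic",
    "combined_probability",
    "RARE_FREQUENCY_WARNING",
]


def intrinsic_probability(odds_ratio: float, K: float) -> float:
    """Intrinsic probability that a rare risk variant causes disease.

    p_rare = K(OR - 1) / (K(OR - 1) + 1).  Only risk variants (OR > 1) are in
    scope: the model treats the variant as an independent cause of disease,
    which has no analogue for protective alleles.
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    if odds_ratio <= 1.0:
        raise ValueError(
            "protective or null rare variants are out of model scope "
            f"(odds ratio must exceed 1, got {odds_ratio})"
        )
    t = K * (odds_ratio - 1.0)
    return t / (t + 1.0)


@dataclass(frozen=True)
class RareVariant:
    """A rare risk allele with its derived intrinsic probability."""

    name: str
    odds_ratio: float
    p_rare: float
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.odds_ratio <= 1.0:
            raise ValueError(
                f"rare variant {self.name!r}: odds ratio must exceed 1"
            )
        if not (0.0 < self.p_rare < 1.0):
            raise ValueError(
                f"rare variant {self.name!r}: intrinsic probability must lie in (0, 1)"
            )
        if self.allele_frequency is not None and self.allele_frequency > RARE_FREQUENCY_WARNING:
            logger.warning(
                "rare variant %s has allele frequency %.4g > %.3g; the "
                "fixed-prevalence assumption may not hold",
                self.name, self.allele_frequency, RARE_FREQUENCY_WARNING,
            )

    @classmethod
    def from_odds_ratio(
        cls,
        name: str,
        odds_ratio: float,
        K: float,
        allele_frequency: Optional[float] = None,
    ) -> "RareVariant":
        """Build a variant, deriving p_rare from its odds ratio and prevalence K."""
        return cls(name, odds_ratio, intrinsic_probability(odds_ratio, K),
                   allele_frequency)


def combine_intrinsic(variants: Sequence[RareVariant]) -> float:
    """Joint intrinsic probability of independent rare variants.

    p_rare = 1 - prod_j (1 - p_rare,j).  Carrying more than one independent
    rare variant is unlikely in practice, but the combination is well defined.
    """
    if len(variants) == 0:
        raise ValueError("at least one rare variant is required")
    return float(1.0 - np.prod([1.0 - v.p_rare for v in variants]))


def combined_probability(p_prs, p_rare: float):
    """Disease probability of a rare-variant carrier with PRS probability p_prs.

    P = p_prs + p_rare (1 - p_prs): the union of two independent causes.
    Monotone in both arguments; ranges over [p_rare, 1].
    """
    p_prs = np.asarray(p_prs, dtype=float)
    if np.any((p_prs < 0) | (p_prs > 1)):
        raise ValueError("PRS-based probability must lie in [0, 1]")
    if not (0.0 <= p_rare <= 1.0):
        raise ValueError("intrinsic probability must lie in [0, 1]")
    out = p_prs + p_rare * (1.0 - p_prs)
    return float(out) if out.ndim == 0 else out
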