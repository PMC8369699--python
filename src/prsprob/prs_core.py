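"""Polygenic risk score computation, sample moments and moment algebra.

A polygenic risk score (PRS) is a per-individual weighted sum of risk-allele
dosages, the weights being per-SNP log odds ratios from an independent GWAS.
This module computes PRS from genotype dosages, summarises score sets by
mean/variance in labelled groups (cases, non-cases, population), standardises
scores against population moments, and converts between (cases, non-cases)
and (cases, population) parameterisations — the latter is what one has when
the reference controls are unscreened population samples containing an
unknown fraction of cases.

Conventions
-----------
* PRS_j = (1/N_snps) * sum_i g_ij * beta_i, with g_ij in {0, 1, 2} counting
  copies of the named effect allele.
* Sample variance uses the 1/N divisor (population variance), not 1/(N-1).
  Downstream calibration only requires that moments be internally consistent,
  but individual-data scoring follows this convention exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GroupLabel = Literal["cases", "noncases", "population"]

__all__ = [
    "EffectWeight",
    "GenotypeMatrix",
    "ScoreSet",
    "GroupMoments",
    "compute_prs",
    "sample_moments",
    "infer_noncase_moments",
    "mixture_moments",
    "standardize",
]


@dataclass(frozen=True)
class EffectWeight:
    """Per-SNP effect-size weight: log odds ratio for one effect allele."""

    snp_id: str
    effect_allele: str
    beta: float
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError(f"beta for SNP {self.snp_id!r} must be finite")
        if self.allele_frequency is not None and not (0.0 < self.allele_frequency < 1.0):
            raise ValueError(
                f"allele frequency for SNP {self.snp_id!r} must lie in (0, 1)"
            )


@dataclass
class GenotypeMatrix:
    """Dosage matrix: individuals x SNPs, entries count effect-allele copies."""

    individual_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # shape (n_individuals, n_snps), values in {0, 1, 2}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_ids)} SNPs"
            )
        if np.issubdtype(self.dosages.dtype, np.integer):
            bad = (self.dosages < 0) | (self.dosages > 2)
        else:
            bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]!r} for individual "
                f"{self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r}; "
                "dosages must be 0, 1 or 2"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class ScoreSet:
    """Per-individual PRS values, optionally labelled case (True) / control (False)."""

    values: np.ndarray
    labels: Optional[np.ndarray] = None  # boolean, True = case
    n_snps: Optional[int] = None
    individual_ids: Optional[list[str]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("PRS values must be one-dimensional")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool)
            if self.labels.shape != self.values.shape:
                raise ValueError("labels must align one-to-one with values")
        if self.individual_ids is not None and len(self.individual_ids) != len(self.values):
            raise ValueError("individual ids must align one-to-one with values")

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    def subset(self, case: bool) -> "ScoreSet":
        """Scores of cases (case=True) or controls (case=False)."""
        if self.labels is None:
            raise ValueError("score set carries no case/control labels")
        mask = self.labels if case else ~self.labels
        return ScoreSet(self.values[mask], np.full(mask.sum(), case), self.n_snps)


@dataclass(frozen=True)
class GroupMoments:
    """Mean and variance of the PRS in one labelled group."""

    label: GroupLabel
    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.label not in ("cases", "noncases", "population"):
            raise ValueError(f"unknown group label {self.label!r}")
        if not (np.isfinite(self.mean) and np.isfinite(self.variance)):
            raise ValueError("moments must be finite")
        if self.variance <= 0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def compute_prs(genotypes: GenotypeMatrix, weights: Sequence[EffectWeight]) -> ScoreSet:
    """Score each individual: PRS_j = (1/N_snps) * sum_i g_ij beta_i.

    Every SNP in the genotype matrix must have exactly one weight; the
    1/N_snps divisor is part of the score definition here.
    """
    if genotypes.n_snps == 0:
        raise ValueError("cannot score an empty SNP set")
    by_id = {w.snp_id: w for w in weights}
    if len(by_id) != len(weights):
        seen: set[str] = set()
        dup = next(w.snp_id for w in weights if w.snp_id in seen or seen.add(w.snp_id))
        raise ValueError(f"duplicate weight for SNP {dup!r}")
    missing = [s for s in genotypes.snp_ids if s not in by_id]
    if missing:
        raise ValueError(f"no weight supplied for SNP(s): {', '.join(missing[:10])}")
    beta = np.array([by_id[s].beta for s in genotypes.snp_ids], dtype=float)
    # chunk over SNPs so the float64 promotion of a large dosage matrix
    # never materialises at once
    values = np.zeros(genotypes.n_individuals)
    chunk = max(1, 50_000_000 // max(genotypes.n_individuals, 1))
    for j in range(0, genotypes.n_snps, chunk):
        sl = slice(j, j + chunk)
        values += genotypes.dosages[:, sl].astype(float) @ beta[sl]
    values /= genotypes.n_snps
    return ScoreSet(values, n_snps=genotypes.n_snps,
                    individual_ids=list(genotypes.individual_ids))


def sample_moments(scores: ScoreSet, label: GroupLabel) -> GroupMoments:
    """Sample mean and (1/N-divisor) variance of a score set.

    Note the population-variance convention: var = (1/N) sum (x - mean)^2.
    """
    if scores.n_individuals < 2:
        raise ValueError("at least 2 individuals are required to estimate moments")
    mean = float(np.mean(scores.values))
    variance = float(np.mean((scores.values - mean) ** 2))
    return GroupMoments(label, mean, variance)


def mixture_moments(cases: GroupMoments, noncases: GroupMoments, K: float) -> GroupMoments:
    """Population moments of the two-component mixture with case fraction K.

    m_p = K m1 + (1-K) m0
    sigma_p^2 = K sigma1^2 + (1-K) sigma0^2 + K (1-K) (m1 - m0)^2
    """
    if not (0.0 <= K <= 1.0):
        raise ValueError(f"prevalence K must lie in [0, 1], got {K}")
    m1, v1 = cases.mean, cases.variance
    m0, v0 = noncases.mean, noncases.variance
    mean = K * m1 + (1.0 - K) * m0
    variance = K * v1 + (1.0 - K) * v0 + K * (1.0 - K) * (m1 - m0) ** 2
    return GroupMoments("population", mean, variance)


def infer_noncase_moments(
    population: GroupMoments, cases: GroupMoments, K: float
) -> GroupMoments:
    """Recover non-case moments when only unscreened population controls exist.

    Inverts the mixture identities:

        m0       = (m_p - K m1) / (1 - K)
        sigma0^2 = (sigma_p^2 - K sigma1^2)/(1-K) - K (m_p - m1)^2 / (1-K)^2

    Raises if the implied non-case variance is not positive, which signals
    mutually inconsistent summary inputs.
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must lie in (0, 1), got {K}")
    mp, vp = population.mean, population.variance
    m1, v1 = cases.mean, cases.variance
    m0 = (mp - K * m1) / (1.0 - K)
    v0 = (vp - K * v1) / (1.0 - K) - K * (mp - m1) ** 2 / (1.0 - K) ** 2
    if v0 <= 0:
        raise ValueError(
            "inconsistent summary inputs: implied non-case variance "
            f"{v0:.6g} is not positive"
        )
    return GroupMoments("noncases", m0, v0)


def standardize(x, population: GroupMoments):
    """Express PRS in population standard-deviation units: (x - m_p) / sigma_p."""
    if population.variance <= 0:
        raise ValueError("population variance must be positive to standardise")
    out = (np.asarray(x, dtype=float) - population.mean) / population.sd
    return float(out) if out.ndim == 0 else out
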