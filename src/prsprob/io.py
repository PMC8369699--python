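"""File formats, run configuration and the probability-report orchestrator.

Everything here is plumbing: tab-separated weights/genotype/curve files, an
optional VCF dosage source, a flat key-value configuration, and
``run_probability``, which wires the calibration, rare-variant and
genotype-stratification layers together for one run.

Formats
-------
* Weights: TSV with header ``snp_id  effect_allele  beta  maf`` (maf optional).
* Genotypes: TSV, individuals as rows, first column the individual id, one
  dosage column per SNP (header row of SNP ids); or a VCF, in which case
  dosages are extracted from diploid GT fields and flipped (2 - g) when the
  weight's effect allele is the REF allele.  Matching is by SNP id and
  effect allele, never by genomic position.
* Curve tables: TSV ``x_st  probability  raw_probability`` with ``#`` comment
  headers recording alpha, beta, K and the source moments, values at 10
  significant digits.
* Config: flat key-value YAML; the model needs at most ~15 scalars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .apoe_strata import genotype_prevalences
from .prs_core import (
    EffectWeight,
    GenotypeMatrix,
    GroupMoments,
    infer_noncase_moments,
    standardize,
)
from .rare_variants import RareVariant, combine_intrinsic, combined_probability
from .risk_model import (
    CurveTable,
    GridSpec,
    LogisticCurve,
    closed_form_coefficients,
    logistic_probability,
    probability_curve,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "RunConfig",
    "ProbabilityReport",
    "read_weights",
    "read_genotypes",
    "read_rare_variants",
    "read_config",
    "write_curve_table",
    "read_curve_table",
    "run_probability",
]


def read_weights(path: PathLike) -> list[EffectWeight]:
    """Parse a TSV weights file; errors carry the offending line number."""
    weights: list[EffectWeight] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["snp_id", "effect_allele", "beta"]:
            raise ValueError(
                f"{path}: expected header 'snp_id\\teffect_allele\\tbeta[\\tmaf]', "
                f"got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            snp_id, allele = parts[0], parts[1]
            if snp_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate snp_id {snp_id!r}")
            seen.add(snp_id)
            try:
                beta = float(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed beta {parts[2]!r} for SNP {snp_id!r}"
                ) from None
            maf = None
            if len(parts) > 3 and parts[3] not in ("", "NA"):
                maf = float(parts[3])
            weights.append(EffectWeight(snp_id, allele, beta, maf))
    if not weights:
        raise ValueError(f"{path}: no weights found")
    return weights


def _read_genotypes_tsv(path: PathLike) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    individuals = [str(i) for i in df.index]
    snp_ids = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d individual(s) with missing genotypes", n_dropped)
        individuals = [i for i, ok in zip(individuals, complete) if ok]
        values = values[complete]
    return individuals, snp_ids, values.astype(np.int64)


def _read_genotypes_vcf(
    path: PathLike, weights: Sequence[EffectWeight]
) -> tuple[list[str], list[str], np.ndarray]:
    import pysam

    by_id = {w.snp_id: w for w in weights}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        dosage_rows: dict[str, np.ndarray] = {}
        for rec in vf:
            w = by_id.get(rec.id)
            if w is None:
                continue
            alleles = rec.alleles or ()
            if w.effect_allele == rec.ref:
                effect_index = 0
            elif w.effect_allele in (rec.alts or ()):
                effect_index = alleles.index(w.effect_allele)
            else:
                raise ValueError(
                    f"{path}: effect allele {w.effect_allele!r} of SNP {rec.id!r} "
                    f"matches neither REF nor ALT ({alleles})"
                )
            row = np.full(len(samples), -1, dtype=np.int64)
            for k, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue  # missing -> individual dropped later
                row[k] = sum(1 for a in gt if a == effect_index)
            dosage_rows[rec.id] = row
    missing = [s for s in by_id if s not in dosage_rows]
    if missing:
        raise ValueError(
            f"{path}: weighted SNP(s) absent from VCF: {', '.join(missing[:10])}"
        )
    snp_ids = list(by_id)
    mat = np.stack([dosage_rows[s] for s in snp_ids], axis=1)
    complete = ~(mat < 0).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d individual(s) with missing genotypes", n_dropped)
    return [s for s, ok in zip(samples, complete) if ok], snp_ids, mat[complete]


def read_genotypes(
    path: PathLike,
    format: str = "tsv",
    weights: Optional[Sequence[EffectWeight]] = None,
) -> GenotypeMatrix:
    """Read a dosage matrix on the effect-allele convention.

    With weights supplied, the matrix is restricted to the weighted SNPs and
    every weighted SNP must be present; individuals with any missing weighted
    genotype are dropped with a logged count.
    """
    if format == "tsv":
        individuals, snp_ids, mat = _read_genotypes_tsv(path)
        if weights is not None:
            have = set(snp_ids)
            missing = [w.snp_id for w in weights if w.snp_id not in have]
            if missing:
                raise ValueError(
                    f"{path}: weighted SNP(s) absent from genotype file: "
                    f"{', '.join(missing[:10])}"
                )
            order = [snp_ids.index(w.snp_id) for w in weights]
            snp_ids = [w.snp_id for w in weights]
            mat = mat[:, order]
    elif format == "vcf":
        if weights is None:
            raise ValueError("VCF ingestion requires a weights set to orient alleles")
        individuals, snp_ids, mat = _read_genotypes_vcf(path, weights)
    else:
        raise ValueError(f"unsupported genotype format {format!r}")
    if not individuals:
        raise ValueError(f"{path}: no individuals with complete genotypes")
    return GenotypeMatrix(individuals, snp_ids, mat)


def read_rare_variants(path: PathLike, K: float) -> list[RareVariant]:
    """Read a rare-variant descriptor TSV: name, odds_ratio[, allele_frequency]."""
    out: list[RareVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "odds_ratio"]:
            raise ValueError(
                f"{path}: expected header 'name\\todds_ratio[\\tallele_frequency]'"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            af = float(parts[2]) if len(parts) > 2 and parts[2] not in ("", "NA") else None
            try:
                odds = float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed odds ratio {parts[1]!r}"
                ) from None
            out.append(RareVariant.from_odds_ratio(parts[0], odds, K, af))
    if not out:
        raise ValueError(f"{path}: no rare variants found")
    return out


@dataclass
class RunConfig:
    """One probability run: prevalence, source moments, optional risk layers."""

    K: float
    cases: GroupMoments
    noncases: Optional[GroupMoments] = None
    population: Optional[GroupMoments] = None
    rare_variants: list[RareVariant] = field(default_factory=list)
    apoe_frequency: Optional[float] = None
    apoe_odds_ratio: Optional[float] = None
    apoe_genotype: Optional[int] = None  # 0, 1 or 2 risk alleles
    grid: GridSpec = field(default_factory=GridSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0):
            raise ValueError("K must lie in (0, 1)")
        if (self.noncases is None) == (self.population is None):
            raise ValueError(
                "exactly one of non-case or population moments must be supplied"
            )
        if self.apoe_genotype is not None and self.apoe_genotype not in (0, 1, 2):
            raise ValueError("apoe_genotype must be 0, 1 or 2")

    def resolve_noncases(self) -> GroupMoments:
        if self.noncases is not None:
            return self.noncases
        return infer_noncase_moments(self.population, self.cases, self.K)


def read_config(path: PathLike) -> RunConfig:
    """Load a flat key-value config (YAML-compatible subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    cases = GroupMoments("cases", float(raw["m_cases"]), float(raw["var_cases"]))
    noncases = population = None
    if "m_noncases" in raw:
        noncases = GroupMoments(
            "noncases", float(raw["m_noncases"]), float(raw["var_noncases"])
        )
    if "m_population" in raw:
        population = GroupMoments(
            "population", float(raw["m_population"]), float(raw["var_population"])
        )
    grid = GridSpec(
        float(raw.get("grid_lo", -4.0)),
        float(raw.get("grid_hi", 4.0)),
        int(raw.get("grid_n", 161)),
    )
    return RunConfig(
        K=float(raw["K"]),
        cases=cases,
        noncases=noncases,
        population=population,
        apoe_frequency=(float(raw["apoe_f"]) if "apoe_f" in raw else None),
        apoe_odds_ratio=(float(raw["apoe_or"]) if "apoe_or" in raw else None),
        apoe_genotype=(int(raw["apoe_genotype"]) if "apoe_genotype" in raw else None),
        grid=grid,
        seed=int(raw.get("seed", 0)),
    )


def write_curve_table(table: CurveTable, path: PathLike) -> None:
    """Write a curve table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        if table.curve is not None:
            c = table.curve
            fh.write(f"# alpha={c.alpha:.10g}\tbeta={c.beta:.10g}\tK={c.prevalence:.10g}\n")
            fh.write(
                f"# m_cases={c.cases.mean:.10g}\tvar_cases={c.cases.variance:.10g}\t"
                f"m_noncases={c.noncases.mean:.10g}\tvar_noncases={c.noncases.variance:.10g}\n"
            )
        cols = ["x_st", "probability"] + (
            ["raw_probability"] if table.raw_probability is not None else []
        )
        fh.write("\t".join(cols) + "\n")
        for i in range(len(table.x_st)):
            row = [f"{table.x_st[i]:.10g}", f"{table.probability[i]:.10g}"]
            if table.raw_probability is not None:
                row.append(f"{table.raw_probability[i]:.10g}")
            fh.write("\t".join(row) + "\n")


def read_curve_table(path: PathLike) -> CurveTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    raw = df["raw_probability"].to_numpy() if "raw_probability" in df else None
    return CurveTable(df["x_st"].to_numpy(), df["probability"].to_numpy(), raw)


@dataclass
class ProbabilityReport:
    """Per-point probabilities with provenance of curve, prevalence and rare layer."""

    table: pd.DataFrame  # columns: x_st, p_prs, p_combined
    curve: LogisticCurve
    K_effective: float
    rare_variants: list[RareVariant] = field(default_factory=list)
    apoe_genotype: Optional[int] = None

    def write(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# alpha={self.curve.alpha:.10g}\tbeta={self.curve.beta:.10g}\t"
                f"K={self.K_effective:.10g}\n"
            )
            if self.rare_variants:
                names = ",".join(v.name for v in self.rare_variants)
                fh.write(f"# rare_variants={names}\n")
            if self.apoe_genotype is not None:
                fh.write(f"# apoe_genotype={self.apoe_genotype}\n")
            self.table.round(6).to_csv(fh, sep="\t", index=False)


def run_probability(
    config: RunConfig,
    prs_values: Optional[np.ndarray] = None,
    weight_snp_ids: Optional[Sequence[str]] = None,
) -> ProbabilityReport:
    """Evaluate the configured probability model on a grid or on PRS values.

    The base curve is calibrated from the configured moments and prevalence;
    if a high-effect variant genotype is configured, the prevalence is
    replaced by that genotype's stratified value; configured rare variants
    are then folded in as an intrinsic probability.  PRS values are taken on
    the raw score scale of the supplied moments.
    """
    if weight_snp_ids is not None:
        clash = {v.name for v in config.rare_variants} & set(weight_snp_ids)
        if clash:
            raise ValueError(
                f"rare variant(s) also present in the PRS weights set: {sorted(clash)}"
            )
    noncases = config.resolve_noncases()
    K_eff = config.K
    if config.apoe_genotype is not None:
        if config.apoe_frequency is None or config.apoe_odds_ratio is None:
            raise ValueError("apoe_genotype requires apoe_f and apoe_or")
        kg = genotype_prevalences(
            config.K, config.apoe_frequency, config.apoe_odds_ratio
        )
        K_eff = kg.as_tuple()[config.apoe_genotype]
    curve = closed_form_coefficients(config.cases, noncases, K_eff)
    # standardisation always uses the overall-population mixture at K, so
    # stratified and unstratified runs share one axis
    from .prs_core import mixture_moments

    pop = mixture_moments(config.cases, noncases, config.K)
    if prs_values is None:
        x_st = config.grid.points()
        x = pop.mean + x_st * pop.sd
    else:
        x = np.asarray(prs_values, dtype=float)
        x_st = standardize(x, pop)
    p_prs = logistic_probability(curve, x)
    p = p_prs
    if config.rare_variants:
        p = combined_probability(p_prs, combine_intrinsic(config.rare_variants))
    df = pd.DataFrame({"x_st": x_st, "p_prs": p_prs, "p_combined": p})
    return ProbabilityReport(df, curve, K_eff, list(config.rare_variants),
                             config.apoe_genotype)
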