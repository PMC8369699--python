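"""Score individuals from a weights file and a genotype dosage file.

Builds a three-SNP weights table and a two-individual dosage matrix as TSV,
then scores them: PRS_j = (1/N_snps) * sum_i g_ij beta_i.
"""

import tempfile
from pathlib import Path

import prsprob as pp

tmp = Path(tempfile.mkdtemp())
(tmp / "weights.tsv").write_text(
    "snp_id\teffect_allele\tbeta\tmaf\n"
    "rs1\tA\t0.20\t0.30\n"
    "rs2\tC\t-0.10\t0.10\n"
    "rs3\tG\t0.50\t0.45\n"
)
(tmp / "genotypes.tsv").write_text(
    "individual_id\trs1\trs2\trs3\n"
    "sample1\t2\t0\t0\n"
    "sample2\t1\t2\t1\n"
)

weights = pp.read_weights(tmp / "weights.tsv")
genotypes = pp.read_genotypes(tmp / "genotypes.tsv", "tsv", weights)
scores = pp.compute_prs(genotypes, weights)

for ind, value in zip(scores.individual_ids, scores.values):
    print(f"{ind}: PRS = {value:.6f}")

# sample1: (2*0.20)/3 = 0.133333; sample2: (0.20 - 0.20 + 0.50)/3 = 0.166667.
# On their own these numbers are meaningless; they become interpretable only
# against the case/non-case PRS distribution via the probability curve.
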