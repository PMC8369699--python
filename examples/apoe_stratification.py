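"""Genotype-stratified probability curves for a common high-effect variant.

APOE-e4 is too common and too strong to treat as a rare variant: it shifts
the disease prevalence itself.  Under HWE the overall prevalence K splits
into per-genotype prevalences K0 (no risk allele), K1 (one), K2 (two); the
PRS computed without the APOE region then gives one curve per genotype.
"""

import prsprob as pp

K, f, OR = 0.10, 0.18, 3.2  # 65+ prevalence; e4 frequency and odds ratio

kg = pp.genotype_prevalences(K, f, OR)
print(f"K0={kg.K0:.4f}  K1={kg.K1:.4f}  K2={kg.K2:.4f}")
hwe_check = (1 - f) ** 2 * kg.K0 + 2 * f * (1 - f) * kg.K1 + f**2 * kg.K2
print(f"HWE mixture of the three: {hwe_check:.6f} (= K)")

cases = pp.GroupMoments("cases", 0.5, 1.0)      # PRS excluding the APOE region
noncases = pp.GroupMoments("noncases", 0.0, 1.0)
c0, c1, c2 = pp.stratified_curves(cases, noncases, K, f, OR)

print("x_st   e4 non-carrier  heterozygote  e4/e4")
pop = pp.mixture_moments(cases, noncases, K)
for x_st in (-2.0, 0.0, 2.0):
    x = pop.mean + x_st * pop.sd
    print(f"{x_st:+.0f}     {pp.logistic_probability(c0, x):.4f}"
          f"          {pp.logistic_probability(c1, x):.4f}"
          f"        {pp.logistic_probability(c2, x):.4f}")

# An e4/e4 homozygote has a ~3x higher genotype prevalence than the
# population average, so their curve sits above the others at every PRS.
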