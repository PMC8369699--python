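"""Fold a rare high-penetrance variant into the PRS probability curve.

A rare risk variant with odds ratio OR at prevalence K carries an intrinsic
probability p_rare = K(OR-1)/(K(OR-1)+1) of causing disease regardless of
polygenic background.  For a carrier, the curve becomes
P = P_PRS + p_rare (1 - P_PRS), running from p_rare up to 1.
"""

import prsprob as pp

K = 0.10  # 65+ age-group prevalence
sorl1 = pp.RareVariant.from_odds_ratio("SORL1", odds_ratio=7.2, K=K)
trem2 = pp.RareVariant.from_odds_ratio("TREM2", odds_ratio=2.46, K=K)
print(f"SORL1 intrinsic probability: {sorl1.p_rare:.4f}")
print(f"TREM2 intrinsic probability: {trem2.p_rare:.4f}")

cases = pp.GroupMoments("cases", 0.5, 1.0)
noncases = pp.GroupMoments("noncases", 0.0, 1.0)
curve = pp.closed_form_coefficients(cases, noncases, K)

print("x_st   no variant  SORL1 carrier  TREM2 carrier")
pop = curve.population
for x_st in (-3.0, 0.0, 3.0):
    x = pop.mean + x_st * pop.sd
    p = pp.logistic_probability(curve, x)
    p_s = pp.combined_probability(p, sorl1.p_rare)
    p_t = pp.combined_probability(p, trem2.p_rare)
    print(f"{x_st:+.0f}     {p:.4f}      {p_s:.4f}         {p_t:.4f}")

# At the lowest PRS a SORL1 carrier keeps a ~0.38 probability of disease —
# the variant's own penetrance floor — while a non-carrier is near 0.
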