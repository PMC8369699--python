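"""Calibrate a probability-of-disease curve from five summary numbers.

Inputs are the disease prevalence and the PRS mean/variance in cases and in
non-cases — no individual-level genotypes.  The closed form converts them to
logistic coefficients (alpha, beta); the curve is then tabulated on a
standardised PRS axis (population SD units).
"""

import prsprob as pp

cases = pp.GroupMoments("cases", mean=0.5, variance=1.0)
noncases = pp.GroupMoments("noncases", mean=0.0, variance=1.0)
K = 0.10  # disease prevalence, e.g. Alzheimer's disease in the 65+ age group

curve = pp.closed_form_coefficients(cases, noncases, K)
print(f"alpha = {curve.alpha:.6f}   beta = {curve.beta:.6f}")

table = pp.probability_curve(curve, grid=pp.GridSpec(-3, 3, 7))
print("x_st   P(disease)")
for x, p in zip(table.x_st, table.probability):
    print(f"{x:+.1f}    {p:.4f}")

# Reading: an individual 3 population SDs below the mean PRS has a
# probability of disease near the bottom value; 3 SDs above, near the top.
# With identical case/non-case moments the curve would be flat at K.
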