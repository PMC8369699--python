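"""Check the closed form against logistic regression on simulated genotypes.

Simulates a balanced case/control sample of independent HWE genotypes,
scores a PRS, and compares the closed-form probability curve against three
regression procedures of increasing abstraction: ML logistic regression on
the simulated PRS, ML logistic regression on normal score draws, and the
density-weighted logit-link projection.  A smaller sample than a full study
is used here so the example runs in seconds.
"""

import prsprob as pp

config = pp.prs_like_scenario(n_cases=2000, n_controls=2000, seed=1,
                              n_weak=2000, n_strong=39)
report = pp.validate(config, K=0.10)

print(report.summary())
print()
m1, m0 = report.moments["cases"], report.moments["noncases"]
print(f"simulated case PRS:    mean={m1.mean:.5f} sd={m1.sd:.5f}")
print(f"simulated control PRS: mean={m0.mean:.5f} sd={m0.sd:.5f}")

# The 'max |dP|' lines give the largest pointwise probability difference on
# the standardised [-4, 4] axis.  The weighted-logit row is ~1e-14: the
# closed form IS that projection.  The two sampling rows shrink as 1/sqrt(n).
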