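# prsprob

Calibrated probability-of-disease curves from polygenic risk score (PRS)
summary statistics, with separate handling of rare high-penetrance variants
and APOE-style common high-effect variants.

## The problem

A PRS — a weighted sum of risk-allele dosages with GWAS log odds ratios as
weights — has no absolute meaning: its scale depends on the SNP set and the
study that produced the weights, so scores are not comparable between
studies and do not tell an individual their risk. What *is* comparable is
the probability of disease given the score. `prsprob` computes that
probability from five summary numbers — the disease prevalence $K$ and the
PRS mean and variance in cases $(m_1, \sigma_1^2)$ and in non-cases
$(m_0, \sigma_0^2)$ — with no individual-level genotype data required.

It is written for statistical geneticists and clinical-risk modellers
working with diseases such as Alzheimer's, where prevalence varies strongly
with age and genotype group, rare variants (SORL1, TREM2, APP/PSEN) carry
high penetrance, and APOE-ε4 is too strong and too common to fold into the
PRS.

## The model

Assuming the PRS is normal within cases and non-cases, Bayesian inversion
gives the raw probability of disease at score $x$:

$$\hat P(x) = \frac{K\,p_1(x)}{K\,p_1(x) + (1-K)\,p_0(x)}.$$

Projecting its log odds onto a line, weighted by the population mixture
density $p_p = K p_1 + (1-K)p_0$, yields the logistic model
$P(x) = 1/(1+e^{-(\alpha+\beta x)})$ with closed-form coefficients

$$\beta = \frac{m_1-m_0}{\sigma_p^2}\Big(K(1-K)\big(\tfrac{r_0+r_1}{2}-1\big) + K\tfrac{\sigma_1^2}{\sigma_0^2} + (1-K)\tfrac{\sigma_0^2}{\sigma_1^2}\Big),$$

$$\alpha = \log\frac{K\sigma_0}{(1-K)\sigma_1} + \tfrac12\big((r_0-1)K + (1-r_1)(1-K)\big) - m_p\beta,$$

where $r_0 = (\sigma_1^2+(m_1-m_0)^2)/\sigma_0^2$,
$r_1 = (\sigma_0^2+(m_1-m_0)^2)/\sigma_1^2$ and $(m_p,\sigma_p^2)$ are the
population mixture moments. When the group variances are equal this is
exactly the discriminant-analysis log odds; in general it is the best
density-weighted linear approximation to a quadratic log-odds function.

On top of the base curve:

* **Unscreened controls** — if only case and whole-population moments are
  known, the non-case moments are recovered by inverting the mixture
  identities.
* **Rare variants** — a rare risk variant with odds ratio OR has intrinsic
  probability $p_\text{rare} = K(\mathrm{OR}-1)/(K(\mathrm{OR}-1)+1)$ of
  causing disease; a carrier's curve is
  $P_\text{PRS} + p_\text{rare}(1-P_\text{PRS})$, running from
  $p_\text{rare}$ to 1.
* **High-effect common variants** — the prevalence is split into
  per-genotype values $K_0, K_1, K_2$ under Hardy–Weinberg equilibrium in
  the population and in non-cases, and one curve is calibrated per genotype
  with shared variant-excluded PRS moments.
* **Validation** — a simulation ladder (HWE genotype simulation → PRS → ML
  logistic regression; normal score sampling → ML regression; weighted
  logit-link projection) quantifies how closely the closed form tracks
  regression on individual-level data.

## Worked example

```python
import prsprob as pp

cases = pp.GroupMoments("cases", mean=0.5, variance=1.0)
noncases = pp.GroupMoments("noncases", mean=0.0, variance=1.0)
curve = pp.closed_form_coefficients(cases, noncases, K=0.10)
```

prints, via `python examples/closed_form_curve.py`:

```
alpha = -2.322225   beta = 0.500000
x_st   P(disease)
-3.0    0.0216
-2.0    0.0353
-1.0    0.0572
+0.0    0.0914
+1.0    0.1429
+2.0    0.2165
+3.0    0.3142
```

With these summary parameters (cases half a population SD above non-cases,
10% prevalence), an individual 3 SDs below the population mean PRS has a
2.2% probability of disease and one 3 SDs above has 31.4%; the curve passes
through 9.1% near the mean. Folding in a SORL1-like rare variant (OR 7.2,
`examples/rare_variant_carriers.py`) lifts the low-PRS end to its intrinsic
probability 0.38; APOE-style stratification at ε4 frequency 0.18 and OR 3.2
(`examples/apoe_stratification.py`) splits K = 0.10 into genotype
prevalences 0.052 / 0.188 / 0.304 and a curve per genotype.

Each script in `examples/` is a self-contained narrative of one capability;
a thin CLI (`prsprob score|fit|curve|prob|apoe|infer-controls|simulate|validate`)
exposes the same operations on files.

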