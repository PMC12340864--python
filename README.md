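# eqtlpower

Power analysis for expression quantitative trait locus (eQTL) studies,
and what that power means for GWAS colocalization.

Most eQTL studies enroll hundreds of individuals, enough to find at
least one signal per gene but far too few to find the many weaker,
more distal regulatory signals that look like GWAS hits. This package
provides the quantitative machinery to reason about that gap:

* **Signal strength.** Any eQTL signal is summarized by the Pearson
  correlation *r* between allele count and standardized expression.
  Under Hardy–Weinberg equilibrium, `r = β·√(2·MAF·(1−MAF))`, where β
  is the per-allele effect on expression with unit variance, so *r*
  folds effect size and allele frequency into one comparable number;
  *r*² is the fraction of expression variance explained.
* **Analytic power.** The detection test is the two-sided t-test of
  the regression slope (df = n−2). Power is available through the
  noncentral-t route (noncentrality `r·√(n−2)/√(1−r²)`), the Fisher-z
  normal approximation, and the exact sampling distribution of the
  sample correlation under bivariate normality. Minimal sample sizes
  for a target power are found by analytic inversion plus exact
  integer refinement.
* **Detection fractions.** Observed |r| across all signals of a study
  is well described by a log-normal distribution. Integrating power
  against a fitted distribution, `∫ power(r, n)·f(r) dr`, estimates
  the fraction of *all* true signals a study of size n detects.
* **Discovery machinery.** A vectorized marginal scan, stepwise
  conditional (forward-selection) discovery of multiple signals per
  gene, and a Monte-Carlo empirical power estimator that validates the
  analytic formulas end to end.
* **Colocalization.** A from-scratch approximate-Bayes-factor
  colocalization engine (posteriors PPH0–PPH4 under the
  single-causal-variant model, Wakefield ABFs, log-sum-exp stable) and
  a simulation experiment showing that a larger eQTL study colocalizes
  more GWAS loci — across the whole range of signal strengths, not
  just the strong ones.
* **Synthetic data.** Genotypes with Hardy–Weinberg marginals and
  tunable local LD, rank-inverse-normal (RINT) expression with planted
  effects, and paired eQTL/GWAS summary statistics, all seeded and
  reproducible, so every stage is testable without cohort data.

## Worked example

```python
import numpy as np
from eqtlpower import (
    power, sample_size_for_power, r_from_beta_maf,
    simulate_genotypes, simulate_expression_study, stepwise_conditional_scan,
    detection_fraction, SignalStrengthDistribution,
)

# 1. a strong signal: beta = 0.33 per allele at MAF 0.25
r = r_from_beta_maf(0.33, 0.25)
print(f"r = {r:.3f}, variance explained = {r**2:.3f}")

# 2. power to detect it at various study sizes (alpha = 2e-5)
for n in (100, 500, 2000):
    print(f"power at n={n}: {float(power(r, n)):.3f}")

# 3. sample size for 80% power at a weak signal (r = 0.05)
print("n for 80% power at r=0.05:", sample_size_for_power(0.05, 0.8))

# 4. what fraction of all signals does a 2,000-sample study detect,
#    under a log-normal signal-strength distribution?
dist = SignalStrengthDistribution(mu=-2.3, sigma=0.6)
print(f"detection fraction at n=2000: {detection_fraction(dist, 2000):.3f}")

# 5. find signals in a simulated study and recover the planted effects
g = simulate_genotypes(n=5000, m=20, mafs=0.3, ld_rho=0.3, seed=1)
study = simulate_expression_study(g, causal=[(4, 0.25), (15, 0.12)], noise_seed=2)
for s in stepwise_conditional_scan(g, study.expression):
    print(f"rank {s.rank}: {s.variant_id}  r={s.r:.3f}  p={s.p_value:.2e}")
```

prints

```
r = 0.202, variance explained = 0.041
power at n=100: 0.010
power at n=500: 0.617
power at n=2000: 1.000
n for 80% power at r=0.05: 10416
detection fraction at n=2000: 0.547
rank 1: var_4000  r=0.246  p=4.53e-70
rank 2: var_15000  r=0.132  p=2.77e-22
```

A signal explaining 4% of expression variance is essentially
undetectable at n = 100, a coin flip at n = 500, and certain at
n = 2,000; a weak signal (r = 0.05) needs more than ten thousand
samples. Given a realistic spread of signal strengths, a 2,000-sample
study still finds only about half of all true signals. The stepwise
scan recovers both planted signals with the correct ranks (the rank-1
estimate r ≈ 0.25 illustrates the mild winner's-curse inflation of
detected effects).

The same operations are available on the command line:

```sh
eqtl-power power --r 0.1 --n 2000
eqtl-power samplesize --r 0.05 --power 0.8 --sig-figs 3
eqtl-power table --rs 0.05,0.1,0.2 --ns 500,2000
eqtl-power coloc --trait1 eqtl.tsv --trait2 gwas.tsv
eqtl-power run config.yaml
```

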