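# Methods

## Signal strength

A cis-eQTL signal is modeled as a simple linear regression of
standardized gene expression on allele count (0/1/2). With expression
at unit variance and Hardy–Weinberg genotype variance `2·maf·(1−maf)`,
the per-allele effect β and the genotype–expression correlation are
interchangeable:

    r = β · sqrt(2·maf·(1−maf))

Allele-count coding is assumed throughout; allele frequencies above
0.5 are folded to the minor allele on ingest, flipping the effect
sign. r² is the fraction of expression variance explained, which is
what makes r the right common currency for comparing signals across
allele frequencies and cohorts. Conditionally distinct signals per
gene are represented with a rank (1 = primary), and the r attached to
a conditional signal is its *marginal* correlation, while its β/se are
the conditional estimates from the selection round — the two answer
different questions and are deliberately both kept.

## Power

The detection test is the two-sided t-test of the regression slope,
t = r̂·√(n−2)/√(1−r̂²) with df = n−2. The default significance level
is α = 2×10⁻⁵ two-sided, a typical per-gene threshold for cis scans;
it is a parameter everywhere, never a constant in a formula.

Three routes are implemented:

* `noncentral_t` (default): under a fixed design the statistic is
  noncentral-t with noncentrality r·√(n−2)/√(1−r²). Two-sided power
  is evaluated through the algebraically identical noncentral-F tail
  P(F(1, n−2; λ²) > t²crit), which stays accurate at df in the
  thousands where direct noncentral-t CDFs lose precision, and
  vectorizes over grids and Monte-Carlo draws.
* `fisher_z`: Φ(atanh(r)·√(n−3) − z_crit) + Φ(−atanh(r)·√(n−3) −
  z_crit). Documented approximation; within 0.02 of the noncentral-t
  for r ≤ 0.2 and n ≥ 500, drifting for strong effects at small n.
* `exact`: both genotype score and expression treated as bivariate
  normal; the sampling density of the sample correlation (Fisher's
  1915 distribution, evaluated via `hyp2f1` in log space) is
  integrated over |r̂| > r_crit. This is the most faithful
  small-sample account of the correlation test: it reproduces
  standard printed power tables for this design to within one unit in
  the last printed digit across the full grid, including strong
  effects at n = 100 where the fixed-regressor noncentral-t is off by
  up to one percentage point. It is scalar quadrature, so the fast
  noncentral-t route remains the default for grids and integration.

Sample-size search inverts the Fisher-z formula for an initial guess,
brackets, and bisects to the exact minimal integer under the requested
method, guaranteeing power(n*) ≥ target > power(n*−1). A reporting
helper rounds to 3 significant figures for table-style output.

## Detection fraction

Observed |r| over all signals of a study is modeled log-normally;
`fit_lognormal` uses the closed-form MLE (mean and n-denominator SD of
log|r|). The expected fraction of all signals detected at size n is

    ∫₀¹ power(r, n) · f(r) dr

computed by Gauss–Legendre quadrature on the log-r scale over
[1e-6, 1−1e-6], with the density renormalized to unit mass on (0, 1)
(|r| < 1 by definition; the fitted mass above 1 is negligible for
realistic parameters, and `mass_above_one()` reports it). The rule
starts at 256 points and doubles until successive estimates differ by
less than 1e-6. A σ = 0 distribution is treated as a point mass, which
reduces the integral exactly to the power function — useful both as an
API convenience and as a quadrature oracle.

Two caveats are intentional. First, the fit is to *detected* signals
with no truncation-likelihood correction, so the distribution is
biased toward strong effects and detection fractions derived from it
are optimistic; every serialized fit carries a note saying so.
Second, results at very small effect sizes are sensitive to small
shifts in the fitted parameters.

Decile bins of |r| use inverse-empirical-CDF (type-1) quantiles — the
k-th edge is the ⌈k·n/10⌉-th order statistic — chosen for exact
reproducibility on integer-sized samples. Outer edges are pinned to 0
and 1 and intervals are left-open right-closed, so a value exactly on
an interior edge belongs to the lower decile and every value in (0, 1]
maps to exactly one decile.

## Synthetic data

The generator emulates exactly the structure the analytics assume:

* **Genotypes.** Two haplotypes per individual, each a latent Gaussian
  AR(1) across variants (autocorrelation `ld_rho`) thresholded at
  Φ⁻¹(maf). Marginally each variant is Bernoulli(maf) per haplotype,
  so HWE holds by construction; thresholded-AR correlation gives
  monotonically decaying local LD. This is the simplest mechanism with
  both properties; it makes no attempt at recombination maps,
  population structure, or relatedness.
* **Expression.** Latent trait = Σ βₖ·gₖ + ε with βₖ from the planted
  rₖ at the variant's MAF and Var(ε) = 1 − Σ rₖ², then RINT (Blom
  offset 3/8, average ranks for ties). Planting on the latent scale
  and transforming perturbs the realized correlation by well under
  0.001 at realistic effect sizes (verified against the planted values
  in tests). Architectures with Σ rₖ² ≥ 1 are rejected.
* **Summary-statistic pairs.** Two independent cohorts are simulated
  at a locus (same MAFs and LD); per-variant marginal regressions give
  (β, se) vectors for an eQTL trait and a quantitative GWAS trait with
  a shared or distinct causal variant. Monomorphic draws trigger a
  bounded, warned resampling.

All randomness descends from explicit integer seeds through
`numpy.random.Generator`; no global state is touched. What passing
tests on these data do *not* show: behavior under population
stratification, relatedness, covariate confounding, case-control
ascertainment, or real LD block structure — none of which the analytic
power model addresses either.

## Scanning

The marginal scan is closed-form vectorized OLS per variant (betas via
centered cross-products, residual variance from the identity
RSS = Syy − β²·Sxx), two-sided t-test with df = n−2; the t statistic
is algebraically identical to the correlation form. Monomorphic
variants are flagged and carry p = 1. The lead variant is the smallest
p, ties broken by smallest genomic position.

Stepwise discovery is forward selection only: each round residualizes
expression and candidate genotypes on the selected leads
(Frisch–Waugh), rescans with df = n−2−k, and stops when the best
conditional p ≥ α or at `max_signals` (default 10). Nearly collinear
candidates (residual genotype variance below 1e-10 of the original)
are dropped with a warning. There is no per-gene permutation or FDR
layer — α is the interface, and a study's multiplicity policy lives
outside the scan. Reported r values for detected signals are upward
biased by selection (winner's curse); simulation reports surface both
planted and estimated values.

`empirical_power` simulates all replicates as one matrix (binomial HWE
genotypes, latent effect, column-wise RINT, closed-form regression)
and reports the detection rate with its binomial standard error. It is
the independent Monte-Carlo oracle for the analytic power module, and
the two agree within 3 binomial SEs across the tested grid.

## Colocalization

Wakefield's approximate Bayes factor per variant: with V = se²,
W = prior effect variance, k = W/(V+W),

    log ABF = ½·log(1−k) + ½·z²·k ,   z = β/se

Priors default to the field-standard p1 = p2 = 1e-4, p12 = 1e-5, with
prior effect SD 0.15 for quantitative traits and 0.2 for case-control
(all configurable). The single-causal-variant enumeration accumulates
H1 = p1·ΣA, H2 = p2·ΣB, H3 = p1·p2·(ΣA·ΣB − ΣAB), H4 = p12·ΣAB
entirely on the log-sum-exp scale and normalizes against H0 = 1, so
posteriors are stable for |z| up to 100 and sum to 1 within 1e-9.

The sample-size experiment draws per-locus eQTL strengths from a
log-normal signal-strength distribution (default μ = −2.3, σ = 0.6 —
median r ≈ 0.10 with a heavy weak-signal tail, matching the shape
reported by large blood cohorts), shares the GWAS causal variant at a
configurable fraction of loci (default 30%), and compares two eQTL
study arms (defaults 420 vs 2,256, the sizes of a component study and
a meta-analysis of subcutaneous-adipose eQTL). A GWAS locus counts as
colocalized when PPH4 ≥ 0.5 against a *detected* eQTL (lead p < α),
mirroring the "at least one eQTL" counting rule. Defaults for the
nuisance dimensions (40 variants per locus, LD ρ = 0.5, GWAS arm of
10,000 with r_gwas = 0.06 — a GWAS z ≈ 6 signal) keep the GWAS side
well powered so the contrast isolates eQTL detection; the experiment
at 200 loci runs in seconds-to-minutes on one core. Because sharing is
independent of r, the proportion of detected signals that colocalize
is flat across deciles of r — the experiment's second diagnostic.
Conditional (multi-signal) loci are out of the experiment's scope;
each simulated locus carries one eQTL signal.

## Characterization

Per-decile summaries of detected signals: counts, median and quartile
TSS distances (absolute, per the usual presentation; signed distances
are not retained in the table format), the fraction of signals at or
beyond a configurable distance threshold (default 36 kb, an external
GWAS-derived median, inclusive comparison), and overlap proportions
with promoter/enhancer BED tracks plus high-pLI and TF gene flags.
BED intervals are 0-based half-open; variant positions are 1-based and
converted on ingest, with a variant treated as a length-1 interval and
membership meaning strict containment. Annotation overlap uses the
lead variant only — no LD expansion or credible sets.

## Pipeline

`eqtl-power run config.yaml` executes requested stages in dependency
order (simulate → scan → fit_dist → detect_frac → coloc_exp →
characterize) and writes a versioned JSON report containing every
parameter, seed, surfaced default (α, coloc priors, RINT offset), and
a SHA-256 checksum of each output, so reruns with identical
configuration are verifiably identical. Exit codes: 0 success, 2
configuration error, 3 numeric failure. All outputs are TSV/JSON; no
figures are produced.

## Known limitations

* The power model assumes a single tested variant per signal; it does
  not account for the multiple-testing burden across variants within
  a cis-window or for LD between tests.
* No covariates, PEER factors, mixed models, or relatedness.
* The detection-fraction estimate inherits the truncation bias of the
  fitted distribution (see above) and should be read as optimistic.
* The colocalization engine is single-causal-variant per trait;
  loci with allelic heterogeneity require residualized inputs, which
  the experiment sidesteps by planting one signal per locus.
* Sample-size tables at 3 significant figures can differ by one unit
  in the last digit between power formulas (noncentral-t vs exact vs
  Fisher-z); the bracketing guarantee holds per method.
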