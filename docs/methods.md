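# Methods

## Generation-mean model

The package works in the F2-reference parameterization of line cross
theory: every composite effect is a deviation from the F2 generation mean
μ. A generation is characterized by its source index θ_S = 2S − 1 (S =
proportion of the genome from P1) and hybridity index θ_H = 2H − 1 (H =
expected heterozygosity). The coefficient of an effect with `a` additive
and `d` dominance factors in a generation's expected mean is θ_S^a · θ_H^d,
with 0^0 = 1 so μ always enters with coefficient 1. The seven standard
generations are hard-coded with exact rational (S, H); custom generations
can be declared by supplying (S, H) or (θ_S, θ_H) directly.

All coefficients, contrast variances and normal-equation inverses are
computed in exact rational arithmetic (`fractions.Fraction`, plus a small
Gauss–Jordan routine in `rilcross.exact`). This makes the design-comparison
results — the 92/94/56% individual and 63/92/94/79% joint variance
reductions — identities rather than numerical approximations. Floating
point is used only once observed data enter.

The idealized RIL generation uses θ_H = −1 exactly (infinitely many selfing
generations). `finite_selfing_hybridity(t)` provides the finite-t
alternative, H = (1/2)^t, for sensitivity analysis; t = 1 reproduces the
F2. Note 1 − (1/2)^t gives 98.44% homozygosity at t = 6 and 99.61% at
t = 8; figures sometimes quoted as ~99.8–99.96% for six-to-eight selfing
generations correspond to no integer t under this recursion and are not
used anywhere.

The marker-based source-index estimate for a RIL population is
2·(P1 alleles / total alleles) − 1, counting two alleles per homozygous
call and one per heterozygous call and excluding missing calls from
numerator and denominator alike. It assumes markers sample the genome
evenly; no weighting for uneven marker spacing is implemented. Residual
heterozygosity above 5% (configurable) triggers a warning, not an error.

## Closed-form scaling tests

The estimator catalogs are linear contrasts of generation means, exact and
unbiased by construction (each coefficient vector times the full design
matrix equals the target effect's indicator; this identity is enforced in
the test suite with rational arithmetic). The traditional catalog uses the
six classical generations; the RIL catalog replaces the D, AA and DD
contrasts with shorter ones:

| effect | traditional | Var/σ² | RIL-based | Var/σ² |
|---|---|---|---|---|
| μ | z̄F2 | 1 | same | 1 |
| A | z̄B1 − z̄B2 | 2 | same | 2 |
| D | z̄F1/2 − (z̄P1+z̄P2)/4 + z̄B1 + z̄B2 − 2z̄F2 | 6.375 | (z̄F1 − z̄RIL)/2 | 0.5 |
| AA | 2(z̄B1 + z̄B2 − 2z̄F2) | 24 | (z̄P1+z̄P2)/2 − z̄RIL | 1.5 |
| AD | (z̄P2−z̄P1)/2 + z̄B1 − z̄B2 | 2.5 | same | 2.5 |
| DD | z̄F1/2 + z̄F2 + (z̄P1+z̄P2)/4 − z̄B1 − z̄B2 | 3.375 | (z̄F1+z̄RIL)/2 − z̄F2 | 1.5 |

AD cannot be shortened because the RIL mean, having θ_S = 0, carries no
additive-by-dominance information. Among the unbiased contrasts on the
stated generation subsets these are the minimum-variance choices; any
observationally equivalent alternative would share the same variances.

Estimates use Var(z̄_g) = s²_g / n_g with unbiased sample variances;
generation means are treated as independent (individuals are never shared
between generations — documented, not checked). The t statistic is
estimate/SE. Three df policies are available:

* `satterthwaite` (default): Welch–Satterthwaite across the contributing
  generation means — standard practice for a linear combination of means
  with unequal variances;
* `pooled`: Σ(n_g − 1) over contributing generations;
* `paper`: df = 1, preserving the convention of treating the statistic as a
  1-df t test regardless of sample size (a deliberately conservative
  simplification; retained for comparability, not recommended).

Tests are two-sided by default (the null is "effect = 0" without
direction); one-sided alternatives are available. A zero SE is reported as
a degenerate estimate with undefined p, never as infinite evidence.

## Joint scaling

`fit_joint` solves **Y** = **Xβ** by OLS ((X'X)⁻¹X'Y) or WLS
((X'V⁻¹X)⁻¹X'V⁻¹Y with V = diag(SE²) of the generation means; the default,
appropriate for unequal sample sizes). For OLS the reported covariance
still propagates the supplied per-generation variances through the
projection (sandwich form), so equal-weight fitting does not silently
pretend homoscedasticity. Goodness of fit is χ² = Σ(yᵢ−ŷᵢ)²/Var(z̄ᵢ) on
df = #generations − #parameters — the standard joint-scaling convention. A
saturated system (df = 0) is flagged explicitly; its residuals are zero by
construction and no p-value is reported.

Designs are checked for identifiability by SVD with a relative tolerance of
1e−10; a rank-deficient design raises an error naming the confounded effect
columns rather than returning a pseudo-inverse fit.

`sequential_model_search` fits the nested hierarchy
[μ,A] → [μ,A,D] → [μ,A,D,AA] → full pairwise model (configurable),
accepting the first model with goodness-of-fit p ≥ α (default 0.05). AA is
added before AD/DD because it is estimable from the widest range of
generation designs. No AIC/BIC selection is offered — adequacy is judged by
the χ² criterion alone. On the six classical generations the full model is
exactly determined, so the joint solution coincides with the closed-form
contrasts (this equivalence is asserted to 1e−10 relative error in the
tests); for the same reason the "traditional" baseline for the joint
variance comparison is the same whether one takes the closed forms or a
six-generation OLS solve.

## Variance and power analysis

`linear_estimator_variance` implements Var(Σcᵢz̄ᵢ) = Σcᵢ²Var(z̄ᵢ) exactly.
The equal-variance mode sets Var(z̄_g) = σ² for every generation regardless
of n — the assumption under which the headline comparisons are derived — and
a realistic mode takes per-generation Var(z̄_g) = s²_g/n_g. Reductions are
reported as 100·(1 − v₂/v₁), rounded to integers for the summary tables
(one decimal internally). The comparison is monotone in the RIL variance: a
very large RIL population (Var(z̄_RIL) → 0) increases the reductions, while
strong transgressive segregation (inflated RIL variance) shrinks them and
can make the RIL design worse; both limits are exercised in the tests.

Power uses the noncentral t: SE from the variance algebra, pooled df,
noncentrality = effect/SE, with a normal-limit fallback where scipy's
noncentral t underflows (large df × ncp). An optional Monte-Carlo mode
verifies the arithmetic by simulating the contrast and its estimated SE
directly. No optimal-allocation solver (choosing n_g subject to total N) is
included.

## Simulators

The composite-effect simulator draws individual phenotypes as generation
mean + N(0, σ_g²), with σ_g² = inflation_g · σ_E². The Gaussian
homoscedastic noise model is this package's choice — the generation-mean
theory itself is distribution-free — and per-generation variance inflation
is provided to mimic segregation variance in F2/RIL. A seed is mandatory;
identical configs give identical tables.

The per-locus simulator draws unlinked diallelic genotypes through the
cross by Mendelian sampling (P1/P2 fixed, F1 heterozygous, F2 and
backcrosses by gamete sampling, RIL by t rounds of selfing from F2
genotypes, one line per founder; t = ∞ fixes every residual heterozygote at
random). Locus values are in the F2-reference metric: genotypic value =
Σ(a_k·s_k + d_k·h_k) with s ∈ {−1,0,+1} (P1-allele count − 1) and
h ∈ {−1,+1} (+1 if heterozygous), plus optional pairwise aa·s_j·s_k,
ad·s_j·h_k, dd·h_j·h_k terms. Because E[s] = θ_S and E[h] = θ_H in every
generation, summed locus values reproduce the composite-effect model
exactly — the simulator returns the implied composites so truth is always
known. Linkage, selection, drift and marker output formats for QTL mapping
are out of scope.

What passing simulation tests do *not* show about real data: real
experiments have non-Gaussian and heteroscedastic environmental variation,
linked loci, block/environment structure, and RIL populations with residual
heterozygosity and mutation accumulation; none of these is emulated beyond
the variance-inflation knob and finite-t RIL option.

## Problem sizes and numerical choices

The validation suite uses n = 10⁴ individuals per generation for parameter
recovery (every estimate within 4 analytic SE of truth), 5000 replicates
for the empirical RIL/traditional D-variance ratio (within 15% of
0.5/6.375) and for the empirical check of the joint-fit variances, 2000
replicates for type-I-error calibration of the pooled-df t-test and for the
χ² goodness-of-fit calibration (Kolmogorov–Smirnov against the nominal
χ²(df) with known unit variances). Hypothesis property tests are bounded to
rational inputs with small denominators so every assertion stays exact. The
full suite runs in well under a minute on one CPU.

Degenerate inputs are handled explicitly rather than silently: all-missing
marker matrices, empty phenotype files, generations with n < 2 (excluded
with a warning), zero SEs (degenerate estimate), saturated models, and
rank-deficient designs each have a defined outcome described above.
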