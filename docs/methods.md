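# Methods

## Model

Phenotypes are modeled as `y_i = z_i'β + E(G | g_i) + ε_i` with i.i.d.
residuals of mean 0 and variance V_ε, independent of the genotypes. The
package concerns the genotype part `E(G|g)` at one or two marker loci with
unphased genotypes and its variance `V(E(G|g))`.

Three equivalent parameterizations of the genotypic-value table
`G_jk = E(G | g = A_jA_k)` (and `G_jkrs` for two loci) are maintained:

1. **GLM (fixed effects).** Dummy codes `w_j` (allele count) and `v_jk`
   (genotype indicator), reference allele A_m omitted. Coefficients are
   contrasts against the reference cell: `μ₀ = G_mm`, `a_j = G_jm − G_mm`,
   `d_jk = G_jk − G_jm − G_km + G_mm`.
2. **GMA (average effects).** Mean-corrected codes `w*_j = w_j − 2p_j`,
   `v*_jj = v_jj − p_j w_j + p_j²`, `v*_jk = v_jk − p_j w_k − p_k w_j +
   2p_jp_k`. Coefficients are frequency-weighted contrasts:
   `μ* = ȳ··*`, `α*_j = ȳ_j·* − ȳ_m·*`, `δ*_jk = d_jk`.
3. **Fisher (constrained).** All-m-allele effects with every
   frequency-weighted sum over any index equal to zero.

The per-parent allele indicators underlying these codes are undefined on
unphased heterozygotes; only their symmetric combinations (w, v and their
centered versions) are ever evaluated, which is what makes the approach
applicable to unphased data.

Two-locus models add all four epistatic blocks as elementwise products of
per-locus codes, in fixed block order A1, D1, A2, D2, AA, AD, DA, DD.
Dominance-type effect arrays are symmetric and only their upper triangles
become design columns, so `ModelSpec.block_df` reports the free-parameter
count of each block (e.g. m−1 for an A block, (m−1)m/2 for a D block over
the non-reference alleles); that is the numerator df of the block F-test.

## Conversions

All flavor conversions are routed through the genotypic-value table:
evaluate the source model at every genotype cell, then extract the target
parameterization. Extraction is uniform: contract the table over uninvolved
allele indices with a weight vector (allele frequencies for GMA, a point
mass on the reference allele for GLM), then apply reference differences
`f[j] − f[m]` over the involved indices. The Fisher flavor instead performs
the frequency-weighted factorial decomposition (main effects first, then
dominance and interaction residuals), which satisfies the zero-sum
constraints identically; the equivalence maps between flavors (e.g.
`α*_j = α_j − α_m`) are verified by tests rather than used as the
implementation. The one-locus printed map
`μ* = μ₀ + 2Σp_j a_j + ΣΣ p_jp_k d_jk`, `α*_j = a_j + Σ_k p_k d_jk` is also
implemented directly as an independent cross-check.

The two-locus GLM→GMA map has no separate closed form here: the
genotypic-value route is exact and fully determined by the two model
equations, and round-trip identities plus the reference design's known
average effects (μ* = 11.72, α*₁ = 1.8, α*₂ = 2) validate it.

## Estimation

Ordinary least squares throughout. `fit_ols` uses `numpy.linalg.lstsq` on
the labeled design matrix (intercept, covariates, blocks); rank deficiency —
typically an empty genotype cell under a saturated model — is a hard error
by default with an opt-in pseudoinverse fallback. The closed-form LSE from
weighted group means applies only to saturated no-covariate models and is
implemented as table extraction on the cell-mean table with estimated allele
frequencies; equality with matrix OLS is property-tested on random complete
datasets (1–2 loci, up to 4 alleles).

Frequencies entering the GMA codes default to the MLEs `p̂_j = n_j·/(2N)`
from the same dataset, overridable with known population values. MLEs and
the disequilibrium measures `D̂_jj = n_jj/N − p̂_j²`,
`D̂_jk = n_jk/(2N) − p̂_jp̂_k`, `D̂_jkrs` are computed in exact rational
arithmetic from integer counts and floated once, so the exact-HWE fixtures
(integer expected counts required; the minimal valid scale is suggested on
error) give `D̂ = 0.0` exactly and the block-diagonality of X'X and the
decomposition `V̂_Y = V̂_A + V̂_D + V̂_ε` can be asserted at machine precision.

Type III sums of squares are computed by explicitly refitting the model
without the block (transparent and adequate at this scale; no sweep
operators). The block F-test is `(SS3/df)/MSE` with the residual df of the
current model; p-values are upper-tail F probabilities and no
multiple-testing correction is applied. A fit whose MSE is zero relative to
the total SS (noiseless or saturated-in-cells data) refuses to produce a
test rather than return a meaningless p-value.

## Variance components

Per-individual fitted components (one inner product per block) are the
random sources; their sample variances and covariances with **denominator
N** estimate the components and their confounding. `V_ε` is the within-cell
SS/N for saturated no-covariate fits and the MSE otherwise; covariate
effects are excluded from the genetic total. Components are sample
variances, hence non-negative by construction — unlike classical ANOVA
estimators on unbalanced data. The same machinery runs under the GLM dummy
coding to quantify how much of the genotypic variance the fixed-effect
partition leaves in covariance terms.

`true_varcomp_enumeration` computes exact population components for a known
value table and genotype distribution by weighting the (at most
m₁(m₁+1)m₂(m₂+1)/4) genotype cells with their probabilities; it is the
oracle for all simulation targets.

## Simulator

Genotypes are i.i.d. multinomial draws over unordered genotype cells;
per-locus tables come from allele frequencies (HWE) optionally shifted by a
disequilibrium array (`p_jj = p_j² + D_jj`, `p_jk = 2(p_jp_k + D_jk)`,
validity checked), or a joint two-locus table can be given directly; two
loci are otherwise independent (gametic equilibrium). Phenotypes add
Gaussian residuals; a broad-sense heritability target is converted via
`V_ε = V_G(1−H²)/H²` with V_G from exact enumeration.

The reference design (`default_study_config`) fixes the study conditions
used by the tests and the acceptance script: two biallelic loci with
allele-1 frequencies 0.4 and 0.2, GLM effects μ₀ = 10 and
a₁ = a₂ = d₁ = d₂ = (aa) = 1 (all other epistasis zero), V_ε = 17.51. Under
it V_G = 3.072 exactly, split 50.625 / 1.875 / 41.667 / 0.833 / 5.0 % across
A1 / D1 / A2 / D2 / AA, and the residual share is 85.1%. What the simulator
does **not** emulate: linkage/haplotype structure between loci, genotyping
error, missingness, covariate confounding, non-Gaussian residuals, or more
than two loci — passing tests say nothing about robustness to those.

One global seed expands deterministically into per-replicate child seeds
(`numpy.random.SeedSequence.spawn`), so replicated studies are reproducible
and order-independent.

## Model selection study

Forward stepwise with removal: the candidate with the smallest partial-F
p-value (computed in the enlarged model) enters while p < p_enter (0.05);
after each entry, included variables with partial-F p > p_stay (0.05) leave,
worst first; the intercept is always kept. Ties break by canonical column
order; a repeated-model-state guard terminates enter/remove cycles; an
exactly collinear candidate is skipped with a warning. These semantics
follow the classic algorithm; small implementation differences from any
particular statistical package are absorbed by the Monte-Carlo tolerances of
the study-level checks.

Selected models over the eight biallelic two-locus candidates are classified
into types I–X by membership of the five dominant variables (w1, w2, ww, v1,
v2), evaluated with precedence I first. The published category definitions
leave gaps for some subsets (e.g. {w1, w2, v1} without ww); here each
category's "but not" clauses are restricted to the w1/w2/ww pattern (the v
conditions only differentiate I–IV), which reproduces every stated
definition under precedence and makes the assignment total. Under the
reference design at n = 5000 with 1000 replicates the Type-I count is ~74%
(binomial SE ≈ 1.4%), and the GMA coding never produces types VI–VIII
because the orthogonal codes make main effects enter before their products.

## Problem sizes and numerical choices

The test suite and acceptance script run enumeration targets on the 9-cell
exact distribution, the partition contrast on one simulated sample of
100,000, parameter-recovery checks at n = 10³–10⁵ with ±5·SE bands from the
fit's own coefficient covariance, and the selection study at 1000 replicates
of n = 5000 (plus 300-replicate runs at n = 500 for the GLM/GMA ordering
property). Monte-Carlo assertions use 4σ guard bands chosen from binomial or
coefficient standard errors. Tolerances: exact algebraic identities at
1e-10–1e-12; conversion round trips at 1e-10; frequency-sum validation at
1e-12.

## Known limitations

- No phasing, imputation, pedigree structure, or >2 loci.
- No REML/mixed-model machinery and no standard errors for variance
  components (point estimates only).
- The HWD-case variance components use the general fitted-component route
  (sample variances/covariances of fitted components) rather than dedicated
  closed forms; the enumeration oracle validates this route.
- Case-control or otherwise non-random sampling is not adjusted for; the
  estimators assume a simple random sample from the study population.
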