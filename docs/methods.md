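# Methods notes

## Kinship estimator

Pairwise kinship uses the Loiselle et al. (1995) estimator. For allele *a*
at locus *l*, individual *i*'s dosage is p_ila ∈ {0, ½, 1}; with sample
frequency p̄_la over the n_l genotyped individuals,

    F_ij = [ Σ_l Σ_a (p_ila − p̄_la)(p_jla − p̄_la) + Σ_l Σ_a p̄_la(1−p̄_la)/(n_l − 1) ]
           / Σ_l Σ_a p̄_la(1−p̄_la)

The second numerator term corrects the downward bias from estimating
allele frequencies on the same sample: the expectation of F_ij over random
pairs is then ≈ 0, which the test suite checks by simulation. The
multilocus value is a ratio of sums, so loci are implicitly weighted by
their polymorphism; monomorphic loci contribute nothing. For a pair, only
loci genotyped in *both* individuals enter the sums (allele frequencies
are still computed on all genotyped individuals per locus). A pair sharing
no polymorphic genotyped locus gets NaN and is dropped from downstream
statistics with a reported count.

## Distance classes, correlogram, regression

- Classes are equal-pair-count (quantile) bins, default 7 classes with at
  least 100 pairs each; the class count is reduced with a warning when the
  sample cannot support it. Equal counts equalize the power of the
  per-class permutation tests.
- Zero-distance pairs (co-located stems) are excluded everywhere and
  counted; kinship at d = 0 mixes clonality/sibship signal that the
  log-distance model cannot represent.
- The slope b_log is fit by OLS over **all pairwise points**, not class
  means, matching the convention of the standard SGS software; class means
  are for visualization. The **natural logarithm** is used throughout;
  b from a log10 fit is b_ln·ln(10), asserted by test. This matters because
  Sp = −b_log/(1 − F_1) is compared across studies.
- F_1 is the mean kinship of the first equal-count class. Its upper bound
  is reported alongside, because F_1 (hence Sp) depends on it.
- Inference permutes individual locations among individuals (equivalently,
  multilocus genotypes among locations): the multiset of kinship values is
  preserved exactly and only their pairing with distances is randomized.
  P-values are two-sided with add-one correction,
  p = (#{|T*| ≥ |T_obs|} + 1)/(n_perm + 1); per-class deviations are
  measured from the permutation grand mean, which is invariant across
  permutations. Default 10,000 permutations, seeded and reproducible.

## Sp, neighborhood size, and dispersal

Sp = −b_log/(1 − F_1) and Nb = 1/Sp (reported for Sp > 0; non-positive Sp
is flagged as "no positive SGS"). Under two-dimensional isolation by
distance, Nb = 4π·De·σ², with De the effective density (ind/m²) and σ the
axial parent–offspring dispersal SD. The iterative σ estimator alternates:

1. Nb = −(1 − F_1)/b over the active distance range, σ = √(Nb/(4π·De));
2. restrict the active range to (σ, 20σ) ∩ data extent and refit b;

stopping when σ changes by < 0.1% (relative) or after 100 iterations. The
(σ, 20σ) window is the range over which the kinship decay is approximately
linear in ln(d) under the Wright–Malécot model. A non-negative slope at
any iteration, or an active range covering fewer than 3 distance classes,
aborts with a non-convergence flag (σ = NaN) rather than an arbitrary
value. Tolerance and iteration cap are package choices; the procedure
itself follows the established restricted-range convention. For field data
De defaults to D/4 (Ne/N = 0.25), the conventional value for natural plant
populations; the ratio is configurable.

## Diversity statistics

- H_E is Nei's unbiased estimator (2n/(2n−1))(1 − Σp²); rarefied allelic
  richness is the exact hypergeometric expectation
  Σ_a [1 − C(N−N_a, g)/C(N, g)], validated against exhaustive subsample
  enumeration.
- F-statistics are Weir & Cockerham (1984) variance components (a, b, c)
  summed over alleles and loci; multilocus estimates are ratios of summed
  components, never means of per-locus ratios. With a single population
  the among-population component vanishes and f = 1 − c/(b+c) remains the
  within-population inbreeding estimate. Jackknife-over-loci SEs accompany
  multilocus values.
- The F_IS permutation test shuffles **gene copies among individuals
  within the sample, per locus** (random union of gametes). This is the
  only scheme that yields a valid Hardy–Weinberg null for F_IS; permuting
  whole loci, another reading of common software documentation, does not
  randomize heterozygosity. Allele frequencies are invariant under the
  shuffle, so only heterozygote frequencies are recomputed per replicate,
  making 10,000 permutations cheap. P-values are two-sided with add-one
  correction (empirically, both significantly positive and negative F_IS
  occur in real data, e.g. with null alleles present).
- Null-allele frequency from the heterozygote deficit: Brookfield-1
  r = (H_E−H_O)/(1+H_E) (default) or Chakraborty r = (H_E−H_O)/(H_E+H_O).
  Non-positive estimates are reported as-is, flagged "no evidence". The
  modified multilocus F_IS recomputes the variance-component ratio over
  loci not flagged for nulls (pipeline threshold: estimated null frequency
  > 0.05), with a delete-one-locus jackknife SE and normal-theory p.

## The isolation-by-distance simulator

Constant-size population of N = side²·D/10⁴ diploid adults on a square
torus; non-overlapping generations. Each offspring picks a mother
uniformly at random, lands at the mother's position plus axial
Gaussian(0, σ_seed) displacement (wrapped), and picks a father (selfing
excluded; males only when the dioecy switch is on) with probability
proportional to a Gaussian kernel of scale σ_pollen around the mother.
Composite gene-dispersal variance: σ² = σ_seed² + σ_pollen²/2, because
pollen moves paternal genes only while every gene disperses as seed. With
uniform expected reproductive success Ne ≈ N, so the truth record uses
De = D.

Mutation is stepwise (±1 repeat) by default at 10⁻³ per gamete per locus,
with a k-alleles alternative; founders draw from 10 allele states so
polymorphism exists from generation 0. Null-allele corruption applies to
the sampled reads only: each gene copy independently fails to amplify with
the configured rate, (null, x) reads as the false homozygote (x, x) and
(null, null) as missing — so the underlying truth stays intact and the
null-frequency estimators can be validated against the known rate.

Default parameters (side 1000 m, D = 4 ind/ha ⇒ N = 400, σ_seed = 20 m,
σ_pollen = 15√2 m ⇒ σ = 25 m, 12 loci, 200 generations, sample 100)
emulate a low-density tree population with strongly limited dispersal;
200 generations far exceeds the local-structure equilibration time (of
order Nb generations here), though global diversity is not at
mutation-drift equilibrium — irrelevant for SGS, which depends on the
*shape* of the kinship decay. Simulated coordinates carry a `wrap` marker
so distances use the minimum-image (torus) metric; analyzing a torus
sample with planar distances corrupts the long-range correlogram. Field
data is planar and never sets the marker.

What the simulator does **not** emulate: overlapping generations, habitat
heterogeneity, clumped recruitment, selection, genotyping error beyond
null alleles, and real sampling designs (field surveys are not uniform
draws from the population). Recovery tests therefore show that the
estimators are consistent with IBD theory under the model's assumptions,
not that field estimates are unbiased.

## Validation experiment scales

- Simulator recovery: 10 replicate seeds at the default (strong-structure)
  parameters; the median end-to-end Sp estimate is required within 40% of
  1/(4π·De·σ²) = 0.318 and the median iterative σ̂ within 30% of 25 m. At
  Nb ≈ 3 the Wright–Malécot linearization is at the edge of its validity,
  so scatter between replicates is large; the median over seeds is the
  stable quantity.
- Permutation calibration: 1,000 null replicates per test with 199
  permutations each, so the null p-value is exactly uniform on the grid
  (k+1)/200 and the nominal 5% level is achievable exactly; observed
  rejection rates are required within 5% ± 2%.
- The ANOVA type-I check on simulated species tables uses 2,000 replicate
  tables (band 5% ± 1%).

## Comparative meta-analysis conventions

- One record per species; species studied in several populations enter
  with their published cross-population mean Sp (per-population values are
  rarely printed in the source literature).
- The sexual-system contrast is a one-way ANOVA on log Sp (natural log;
  F and p are base-invariant, asserted by test). Log transformation tames
  the right skew and heteroscedasticity of Sp across taxa.
- Ratio brackets are extreme-case: min(numerator)/max(denominator) to
  max(numerator)/min(denominator), plus the ratio of group means.
- The packaged 29-species table stores published values rounded to 4
  decimals; contrasts recomputed from it can differ in the last digit from
  analyses run on unrounded source data.

## Degenerate inputs and tie-breaks

- Half-missing calls (one allele coded 0) are treated as fully missing.
- All-identical pairwise distances collapse to a single class with a
  warning; empty classes after NA removal are dropped with a warning.
- Loci with fewer than 2 genotyped individuals, and populations with n < 2
  at a locus, are excluded from the respective statistics with warnings.
- Datasets join on individual id (inner join, dropped ids reported); fewer
  than 10 joined individuals is a hard error, as is a monomorphic dataset
  for kinship. Per-cluster SGS requires 45 individuals by default
  (configurable), below which the cluster is skipped with a logged reason.
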