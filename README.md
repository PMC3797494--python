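# sgskit

Fine-scale **spatial genetic structure (SGS)** analysis for diploid
codominant markers (microsatellites), written for population geneticists
studying how limited seed and pollen dispersal shapes the spatial
distribution of genotypes — e.g. in low-density tropical tree populations.

## What it computes

Given mapped, genotyped individuals, the package runs the standard SGS
chain:

1. **Pairwise kinship** — the Loiselle et al. (1995) estimator
   *F*<sub>ij</sub>, a ratio of summed allele-dosage cross-products over
   loci with a small-sample bias correction, robust to rare alleles.
2. **Distance classes and correlogram** — equal-pair-count classes
   (default ≥7 classes of ≥100 pairs), per-class mean kinship with a
   permutation envelope and p-values (locations permuted among
   individuals).
3. **Regression and the Sp statistic** — OLS of *F*<sub>ij</sub> on
   ln(*d*<sub>ij</sub>) over all pairs gives the slope *b*<sub>log</sub>;
   with *F*<sub>(1)</sub> the mean kinship of the first distance class,

   *Sp* = −*b*<sub>log</sub> / (1 − *F*<sub>(1)</sub>)

   a sampling-scheme-insensitive measure of SGS intensity, and Wright's
   neighborhood size *Nb* = 1/*Sp*.
4. **Gene dispersal** — under two-dimensional isolation by distance,
   *Nb* = 4π *D*<sub>e</sub> σ², so the axial parent–offspring dispersal
   distance σ is estimated iteratively, restricting the regression to the
   (σ, 20σ) distance range until convergence. The effective density
   defaults to *D*<sub>e</sub> = *D*/4.
5. **Diversity and inbreeding** — allele frequencies, observed/unbiased
   expected heterozygosity, rarefied allelic richness, Weir–Cockerham
   *F*-statistics (variance components, jackknife over loci), a gene-copy
   permutation test for *F*<sub>IS</sub>, Brookfield/Chakraborty null-allele
   estimates and a modified *F*<sub>IS</sub> excluding flagged loci.
6. **Comparative meta-analysis** — species-level *Sp* tables (a packaged
   29-species compilation spanning monoecious and dioecious taxa ships with
   the package), group summaries, extreme-ratio brackets, and a one-way
   ANOVA on log *Sp* contrasting sexual systems.

A spatially explicit forward-time simulator (constant-size population on a
torus, Gaussian seed and pollen kernels, stepwise-mutation microsatellites,
optional null alleles and dioecy) generates datasets with known σ and
density, so every stage can be validated against the Wright–Malécot
prediction *Sp* ≈ 1/(4π *D*<sub>e</sub> σ²).

## Worked example

Simulate a low-density population (4 ind/ha, composite dispersal
σ = 25 m, 12 loci, 100 sampled individuals), then analyze it:

```bash
sgskit simulate --out-dir demo --side 1000 --density 4 \
    --sigma-seed 20 --sigma-pollen 21.2132 --loci 12 \
    --generations 200 --sample-size 100 --seed 42
sgskit sgs --genotypes demo/genotypes.gen --coords demo/coords.tsv \
    --out-dir demo/sgs --density 4 --ne-over-n 1.0 \
    --permutations 1000 --seed 42
sgskit sigma --genotypes demo/genotypes.gen --coords demo/coords.tsv \
    --density 4 --ne-over-n 1.0
```

prints

```
b_log = -0.214685, F1 = 0.2976, Sp = 0.3056 (p = 0.000999)
sigma = 23.53 m, Nb = 2.78 (range 23.5-470.5 m, 6 iterations)
```

The kinship–ln(distance) slope is strongly negative (permutation
p ≈ 0.001): nearby individuals are much more related than distant ones.
The estimated *Sp* = 0.306 sits close to the theoretical
1/(4π·4×10⁻⁴·25²) ≈ 0.318 for the simulated density and dispersal, and the
iterative dispersal estimate recovers σ ≈ 23.5 m against a true 25 m —
with *Nb* ≈ 3 this is an extremely structured population (real tree
populations typically show *Sp* of 0.003–0.07).

The comparative layer runs off the packaged species compilation:

```bash
sgskit meta
```

```
sexual_system  n     mean       sd
       dioecy 15 0.024473 0.016872
      monoecy 14 0.010929 0.008749
ANOVA on log Sp: F = 11.934, df = (1, 27), p = 0.001835
Ficus dioecy/monoecy Sp ratios: 4.3-11.8 (ratio of means 6.5)
```

Dioecious species are, on average, about twice as spatially structured as
monoecious ones; within figs the contrast is several-fold.

`sgskit run-all --config <file>` chains validation, diversity, SGS per
population (and per externally supplied genetic cluster with ≥45
individuals), σ estimation and the meta-analysis, writing delimited tables
plus a key–value summary that reruns bit-identically from the saved config.

## Layout

- `sgskit.datamodel` / `sgskit.io` — genotype+coordinate containers;
  GenePop and delimited-text readers/writers.
- `sgskit.diversity` — heterozygosity, rarefaction, Weir–Cockerham,
  permutation *F*<sub>IS</sub>, null alleles.
- `sgskit.sgs` — kinship, correlogram, regression, *Sp*, σ.
- `sgskit.simulate` — torus IBD simulator and meta-table generator.
- `sgskit.meta` — comparative analysis across sexual systems.
- `sgskit.pipeline` / `sgskit.cli` — orchestration and console interface.

See `docs/methods.md` for the statistical conventions and their rationale.
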