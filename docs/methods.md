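# Methods

## Scope and data model

The package operates on one fixed matrix of biallelic SNP genotypes
(individuals × sites, alternate-allele counts 0/1/2 with a missing
sentinel) read from a GT-only VCF. Genotypes are unpolarised allele
counts; positions are 1-based; every site carries a RAD-locus identifier
(the VCF ID column when present, otherwise the chromosome/locus name).
Upstream locus assembly and genotype calling are out of scope: the
pipeline starts where a variant caller ends.

One consequence is deliberate and documented: toolchains that rebuild
loci de novo per analysis subset produce a *different* site set for every
pairwise comparison, so per-pair denominators from such a pipeline are
not reproducible from a single matrix. Here, per-pair analyses instead
restrict the fixed matrix to sites co-called in the pair (call-rate one
for the pair). The conserved-heterozygosity *fractions* are comparable;
the raw denominators are not.

## Site filters

Three filters, applied in a fixed order so the removal counts in the
filter report are reproducible:

1. **Call rate** — drop sites called in fewer than `min_call_rate`
   (default 0.5) of individuals.
2. **One SNP per locus** — keep the SNP with the smallest position per
   locus (ties by input order). SNPs on one RAD locus are a few dozen bp
   apart and effectively fully linked; keeping one avoids pseudo-
   replication in PCA and F-statistics.
3. **Minor allele frequency** — computed over non-missing calls; the
   boundary is inclusive (a site at exactly `min_maf` = 0.05 is kept).

The relative order of the locus-deduplication and MAF filters is a
convention (they commute only approximately); it is fixed here as
dedup-then-MAF and asserted by the report arithmetic. Filtering is
idempotent, and the output always satisfies both thresholds post hoc.

## Conserved heterozygosity and clonality calls

For a pair (i, j), on co-called sites:

- denominator = sites where at least one of i, j is heterozygous;
- numerator = sites where both are.

This reading makes "conserved" literal — a heterozygous site conserved in
the partner — and bounds the fraction at 1. The alternative denominator
(all co-called sites) is available behind `denominator="co_called"` for
sensitivity analysis. Fractions are reported as percentages rounded
half-up to one decimal.

The classification threshold defaults to 0.485, inclusive, anchored at
the lowest confirmed graft pair rather than a rounded 50%: with dropout
rate d and error rate e, a clone pair is expected near
(1−d)²(1−e)² / (1−(d+e−de)²) of conserved heterozygosity, while an
independent Hardy–Weinberg pair cannot exceed 1/3 in expectation
(per site h²/(2h−h²) ≤ 1/3, h = 2p(1−p); the bound survives averaging
because every per-site ratio obeys it). The gap between ~1/3 and ~0.5 is
what makes a single threshold workable. Clonal groups are connected
components of the thresholded pair graph — transitive closure is the
minimal rule that assembles a multi-member graft lineage from its
pairwise calls. Pairs with no qualifying site are reported with counts
but no verdict, and skipped (with a warning) when building groups.

## Structure: IBS, UPGMA, PCA

IBS similarity at a site is 1 − |g_i − g_j|/2; the pair distance is one
minus the mean over co-called sites (complete case per pair — no
imputation, because imputing toward the mean would shrink exactly the
clone-pair distances the dendrogram is meant to expose). Clustering is
average-linkage (UPGMA) via scipy, with ties resolved deterministically
by input order; the tree exports to Newick and cuts into k groups.

PCA uses Patterson normalisation: per site, subtract 2p̂ and divide by
sqrt(p̂(1−p̂)); missing calls are mean-imputed (zero after centering) —
the standard choice for genotype PCA, where per-pair complete case would
make the covariance matrix non-positive-definite. Monomorphic sites are
excluded (undefined scaling). Eigendecomposition is of the sample×sample
covariance; contribution ratio = eigenvalue / sum of positive
eigenvalues; scores are eigenvectors scaled by sqrt(eigenvalue), so axes
are sign-arbitrary. An unscaled option (`scale=False`) exists for
sensitivity checks. The asymmetry — complete-case IBS, mean-imputed PCA —
is intentional.

## Population statistics

Population allele frequencies are alt-allele count / (2 × called
individuals); a site with zero calls in a population is flagged and
excluded from any statistic involving that population.

**Fis** = 1 − mean(Ho)/mean(He) over sites polymorphic in the population,
with He = 2p̂(1−p̂)·2n/(2n−1). Ratio of means, not mean of ratios: the
per-site ratio is wildly unstable at low frequencies, the ratio of means
is not.

**Fst** is the Weir–Cockerham (1984) estimator with per-site components
a, b, c and the genome-wide ratio Σa/Σ(a+b+c), complete-case per site per
pair (each site uses the individuals called in both populations; sites
with fewer than one call in either population, or mean sample size ≤ 1,
are skipped). Negative estimates are reported as-is — they are
information about null differentiation, not an error. No p-value-based
zeroing or correction is applied, so values on real data will differ
from pipelines that apply one; this is documented rather than emulated
because such corrections are tool-internal and unspecified.

**f3(A; B, C)** per site is (â−b̂)(â−ĉ) − â(1−â)/(n_A−1), with n_A the
number of called alleles in the target; the subtracted term is the
sampling variance of â and removes the upward bias that otherwise masks
admixture at small n (here populations can have single-digit sizes).
**f4** is (â−b̂)(ĉ−d̂) with no correction needed. Genome-wide estimates
are means over usable sites; the f4 arguments may repeat (f4(A,B;C,C) is
identically zero and serves as a self-test), while the f3 target must
differ from both sources.

**Block jackknife.** Standard errors use a weighted delete-one-block
jackknife over consecutive runs of 500 SNPs in matrix order (no genetic
map exists for this kind of de novo dataset; consecutive blocks are the
defensible proxy for local correlation). The trailing partial block is
kept and weighted by its usable-site count; at block size one the
formula reduces exactly to the classic delete-one jackknife, which the
tests verify against an explicit-loop oracle. Z = estimate/SE; with
fewer than two non-empty blocks the estimate is returned with an
undefined SE.

## The simulator

Balding–Nichols: ancestral frequency uniform on (0.05, 0.5], mirrored to
the upper half at random; population k draws
Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), with F_k = 0 returning p exactly.
Individuals are Binomial(2, q·p_sites) draws from ancestry-weighted
frequencies (q one-hot for population members, arbitrary for admixed
individuals). Clones copy a source genotype, then heterozygous calls
drop to a random homozygote with probability d (allelic dropout is
het→hom directional in RAD data), any call is replaced by a uniformly
different code with probability e, and missingness m applies to all
individuals last. Sites are independent — no linkage — and assigned
locus ids in pairs so the one-SNP-per-locus filter has work to do.

The default preset fixes the study conditions: eight populations
(A1, A2, B, C, D, E, F, H) totalling 90 individuals, 4,000 sites, one
ten-member graft lineage (A2: one founder, nine clones), five
independent clone pairs, three individuals of 50/50 A1/D ancestry,
e = 0.01, d = 0.10, m = 0.10. Divergence parameters
(F = 0.06–0.30 across populations) were chosen once to span the
pairwise-Fst scale typical of intraspecific crop/wild collections
(~0.05–0.3); d and e are free parameters of the genotyping process, set
so simulated clone pairs conserve heterozygosity in the empirically
observed range for grafted trees (~50–90%).

What the simulator does **not** emulate: linkage disequilibrium, locus
dropout shared along the genealogy (missingness is i.i.d.), null alleles
correlated between relatives, sequencing depth variation, and de novo
assembly artifacts. Passing tests therefore demonstrate correctness of
the statistics under the generative model, and the clone/non-clone
separation margin under i.i.d. noise — not robustness to every artifact
of real RAD data.

## Numerical and design choices

- All randomness flows from a single integer seed
  (`numpy.random.default_rng`); identical configs give bit-identical
  outputs, which the tests assert at the byte level on written tables.
- Distance matrices are symmetrised exactly ((D+Dᵀ)/2) after vectorised
  computation to remove float-noise asymmetry.
- UPGMA agreement with a brute-force O(N³) average-linkage oracle is
  tested at N ≤ 8; IBS, conserved-het counts and single-block f3 are
  tested against explicit-enumeration oracles; Fst is tested against a
  per-site-loop implementation and a Balding–Nichols Monte-Carlo
  expectation at 50,000 sites (tolerance ±0.02).
- Group assignment from PC axes is not automated (on real data it is an
  interpretive step across several axes); the pipeline reports scores,
  contribution ratios and a dendrogram cut instead.
- Problem sizes in tests and the acceptance script (4,000–5,000 simulated
  sites, 50–100 individuals per population, 50,000-site oracles) are the
  package's desk-scale defaults: large enough that Monte-Carlo noise is
  well inside the stated tolerances, small enough to run in seconds.

## Known limitations

- Single fixed genotype matrix: per-pair denominators are not comparable
  with de novo per-pair assembly pipelines (see above).
- No multiallelic sites, no genotype likelihoods, no phasing — so no
  haplotype-based F-statistics.
- The Fst estimator is plain Weir–Cockerham; pipelines that zero
  non-significant per-site values will report systematically different
  matrices on real data.
- The clonality threshold is a single global constant; collections with
  extreme dropout rates may need it re-anchored from known clone pairs.
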