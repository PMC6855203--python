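# Methods

## Scope

`crossase` implements a desk-scale analogue of a breed-of-origin study in
three-way crossbred pigs. Everything upstream of genotypes and allelic
read counts — read alignment, variant calling and its hard filters,
pileup generation — is out of scope; the package starts from VCF
genotypes, a pedigree, exon intervals and per-SNP allelic counts, and a
synthetic generator produces all of these with ground-truth labels.

## Probability of a heterozygous SNP (PHS)

A crossbreeding scheme is a binary tree whose leaves are breeds and whose
internal nodes are matings with a sire side and a dam side. At one
biallelic locus, a population with genotype frequencies
(p_RR, p_Rr, p_rr) transmits the reference allele with probability
f = p_RR + p_Rr/2 (no Hardy–Weinberg assumption is needed for the leaves;
f is simply the allele frequency among called genotypes). Under random
mating, a cross node's transmitted frequency is the mean of its two
sides', and the root offspring genotype distribution is the product form
P(RR) = f_s f_d, P(Rr) = f_s(1−f_d) + (1−f_s)f_d, P(rr) = (1−f_s)(1−f_d).

The reduction to transmitted frequencies is exact because, with
independent sides, the offspring genotype depends on each side only
through the marginal probability of the transmitted gamete.
`propagate_genotype_distribution` implements the literal alternative —
propagating full genotype distributions through every mating by
enumerating the nine parental genotype pairs and their gametes — and the
test suite holds the two routes to within 1e-12 over random,
deliberately non-HWE genotype triples. Loci with no called genotype in a
leaf breed are excluded from that scheme's table and counted.

PHS distributions are summarised in 20 bins of width 0.05 over [0, 1];
bins are half-open with the last closed, and the bin index is computed as
floor(20·v + 1e-9) clipped to 19 (the epsilon guards values such as 0.35
whose floating representation sits one ulp below a bin edge). Scheme
comparisons correlate per-bin SNP counts (Pearson, raw counts by default
with a log10(count+1) option). Validation against an individual computes
that individual's heterozygote fraction per bin and correlates it with
the bin-mean PHS curve; a sampled-cohort curve would differ from the
bin-mean curve only by binomial noise, so the bin mean is used as the
expected curve. High-PHS markers use a strict threshold (PHS > 0.9 by
default).

## Depth-tail SNP filter

Per-locus total depth is filtered at empirical quantiles: loci strictly
below the `tail_fraction` quantile or strictly above the
`1 − tail_fraction` quantile are removed. The default of 1% per tail
removes ≈2% of loci in total. The filter is applied per input matrix
(cohort) rather than jointly across cohorts.

## Trio phasing

For a heterozygous offspring there are nine ordered (sire, dam) genotype
pairs. Seven are Mendelian-consistent; two (parents homozygous for
opposite alleles) and four (one parent homozygous, the other
heterozygous) identify the parental origin of each allele, and one (both
parents heterozygous) does not. Configurations are counted as ordered
pairs — the only convention under which the 7 = 2 + 4 + 1 decomposition
holds. Offspring loci are labelled with one of six mutually exclusive
classes (not-het, both-hom phasable, one-het phasable, both-het
unphasable, Mendelian error, incomplete). Mendelian-error loci are left
unphased and excluded from downstream ASE, and the per-offspring phased
fraction is reported both with and without them in the heterozygous-locus
denominator (the convention is not otherwise determined). Phased output
lists the paternal allele first (`pat|mat`). Grandparental genotypes are
never used to rescue het×het trios.

At a locus where every breed has f = 0.5, P(both parents heterozygous |
offspring heterozygous) = (0.5·0.5·0.5)/0.5 = 0.25, so the expected
phased fraction is 0.75; the test suite checks this analytic value within
three standard errors, and checks exact (100%) agreement between phased
alleles and the generator's recorded gametes on error-free families.

## ASE calling

SNPs are assigned to genes by exon overlap (BED intervals are 0-based
half-open; VCF positions 1-based). A SNP inside exons of several genes
counts for each and is flagged ambiguous (an exclusion mode exists).
Read-level tables are collapsed so each read counts once, at the
lowest-(chrom, pos) SNP it covers; reads matching neither allele are
discarded and counted. Ref/alt counts are oriented to paternal/maternal
using the trio phase before summing within a gene; rows at unphased SNPs
are dropped and counted.

Genes with fewer than 10 informative reads in a sample are not tested and
fall into the NA class (the three-way classification leaves no other
home for them). The test is the exact two-sided binomial against 1/2:
with n = pat + mat and k = min(pat, mat), p = min(1, 2·P(X ≤ k)) for
X ~ Binomial(n, 1/2), which equals the tail-sum definition
P(|X − n/2| ≥ |k − n/2|) exactly by symmetry. p-values are
Bonferroni-adjusted (min(1, m·p)) within the family of tested genes of
one sample × tissue (a genome-wide family option exists); classification
is ASE iff adjusted p < 0.05, strictly. A high-confidence ASE gene per
tissue is one classified ASE in at least two of the six offspring, and
its allelic ratio is the median over its ASE-classified samples of
max(pat, mat)/(pat + mat) — the higher-expressed-allele fraction, so
ratios are ≥ 0.5 by construction (a signed paternal-fraction column is
retained in the per-record table). Tissue specificity is the fraction of
the union of high-confidence genes found in exactly one tissue.

## Synthetic data generator

The generator defines the study conditions and is itself first-class,
tested code.

**Breed frequencies.** A hierarchical Balding–Nichols model: ancestral
frequency p ~ Uniform(0.05, 0.95) per locus (avoiding
monomorphic-everywhere loci, since only segregating SNPs are of
interest); Duroc drifts from the ancestor at F = 0.30; an unobserved
Landrace/Yorkshire common ancestor drifts at F = 0.05 and each of L and Y
drifts from it at F = 0.05. Each drift step draws
Beta(p(1−F)/F, (1−p)(1−F)/F), i.e. mean p and variance F·p(1−p). These
values put pairwise L–Y differentiation near 0.1 and D-versus-L/Y near
0.3, in the range reported for these commercial breeds, and produce both
the qualitative structure the analysis depends on (L and Y mutually
closer than either is to D) and a realistic, sparse tail of loci near
fixation for opposite alleles in D versus L/Y — the loci that make a
terminal Duroc cross yield high-PHS markers where the two rotations with
a purebred maternal-line sire cannot. Loci are independent: no linkage
or recombination map is simulated, which is sufficient because PHS is a
per-locus quantity. Sex chromosomes are never simulated; loci are laid
out on 18 autosomes at 1 kb spacing (coordinates are arbitrary labels).

**Panels and family.** Purebred panels (default 11 Duroc, 9 Landrace,
10 Yorkshire) are drawn at Hardy–Weinberg equilibrium per breed.
The family is built gamete by gamete: L grandsire × Y granddam → LY dam,
D sire × LY dam → 6 offspring, with every transmitted allele recorded, so
phasing and origin-assignment can be scored exactly. Per-locus total
depth is negative-binomial (means 15×/sample for panels, 38.5×/sample for
the family; dispersion 8) so the depth distribution has tails for the
quantile filter to act on.

**Allelic RNA counts.** 200 genes are laid along the loci with 3–8
exonic SNPs each (genes spanning ≥3 loci leave their middle locus
intronic); this density reflects the several heterozygous exonic SNPs per
gene implied by millions of genome-wide heterozygous SNPs in a crossbred.
20% of genes carry a planted effect with true paternal ratio ρ = 0.8,
each in one random tissue of four (adipose, heart, liver, skeletal
muscle); all other gene × tissue combinations are exactly 0.5. Per
gene × offspring × tissue, a negative-binomial total (mean 100,
dispersion 10) is split Binomial(total, ρ) into paternal/maternal and
distributed multinomially across the gene's SNPs at which that offspring
is heterozygous — counts are only ever emitted at a sample's own
heterozygous loci — then reported as ref/alt via the true phase. This is
the simplest noise model consistent with the binomial test's assumptions:
it does not emulate mapping bias toward the reference allele,
overdispersion of the allelic split itself, or isoform structure, so
passing recovery tests demonstrates correctness of the statistical
machinery, not robustness to those real-data artefacts.

**Determinism.** Every generator is a pure function of its seed; the
pipeline derives independent per-stage seeds from one master seed via
`numpy.random.SeedSequence`, and identical configurations reproduce
byte-identical output files.

## Problem sizes and calibration checks

The default study is 100k loci; tests use 30k–100k loci, chosen to keep
binomial noise well below the margins being asserted. Calibration of the
ASE test uses gene-level totals directly (200 genes × 6 samples per
replicate, negative-binomial mean 100): 500 null replicates estimate the
family-wise error rate of the per-sample Bonferroni procedure (observed
≈0.03–0.04 at α = 0.05, below the nominal level because the exact test is
discrete), and 20 planted-effect replicates estimate sensitivity among
genes with ≥100 reads (≈0.999) and the recovered allelic ratio (≈0.80).

## Known limitations

- Breed divergence parameters are calibrated to qualitative structure,
  not to estimates from any particular panel; absolute marker counts
  scale with both the locus count and the divergence model.
- The generator's site-frequency spectrum (uniform ancestral frequencies)
  is flatter than ascertained resequencing data, so bin-count
  distributions across PHS bins — and hence between-scheme bin-count
  correlations — differ in shape from empirically ascertained SNP sets.
- Trio phasing cannot phase het×het configurations; ~14% of offspring
  het loci remain unphased under the default model and are invisible to
  ASE calling.
- No genotyping error is simulated; Mendelian-error handling is exercised
  by construction in unit tests rather than by an error model.
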